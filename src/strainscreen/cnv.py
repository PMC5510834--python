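"""Qualification and screening of externally produced copy-number calls.

The CNV caller itself is upstream; this module applies the reporting rules:
minimum length, complete-loss deletions or at-least-2-fold duplications,
cross-strain specificity under a reciprocal-overlap rule, coding-sequence
overlap annotation and intersection with a phenotype gene list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .types import CnvCall, CnvKind, ExonModel


@dataclass
class CnvParams:
    """Qualification rules for reportable CNVs.

    Deletions must be complete losses (fold <= ``del_max_fold``, default 0 —
    a small tolerance can be allowed for noisy fold estimates); duplications
    must reach ``dup_min_fold`` copy ratio.  Both must span ``min_length``.
    """

    min_length: int = 5000
    dup_min_fold: float = 2.0
    del_max_fold: float = 0.0

    def __post_init__(self) -> None:
        if self.min_length <= 0:
            raise ValueError("min_length must be positive")
        if self.dup_min_fold <= 1.0:
            raise ValueError("dup_min_fold must exceed 1")

    def passes(self, call: CnvCall) -> bool:
        if call.length < self.min_length:
            return False
        if call.kind is CnvKind.DEL:
            return call.fold <= self.del_max_fold
        return call.fold >= self.dup_min_fold


def qualify_cnvs(calls: Iterable[CnvCall],
                 params: Optional[CnvParams] = None) -> list[CnvCall]:
    """Keep CNV calls meeting the length and fold-change rules (idempotent)."""
    params = params or CnvParams()
    return [c for c in calls if params.passes(c)]


def _reciprocal_overlap(a: CnvCall, b: CnvCall) -> float:
    if a.chrom != b.chrom:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return min(inter / a.length, inter / b.length)


def strain_specific_cnvs(
    a: Sequence[CnvCall],
    b: Sequence[CnvCall],
    min_reciprocal_overlap: float = 0.5,
) -> tuple[list[CnvCall], list[CnvCall]]:
    """CNVs unique to each strain under a reciprocal-overlap matching rule.

    A CNV is shared (not strain-specific) when the other strain carries a
    same-kind CNV with reciprocal overlap of at least
    ``min_reciprocal_overlap`` — breakpoints from read-depth callers are
    imprecise, so exact interval equality would be too strict.
    """
    def specific(own: Sequence[CnvCall], other: Sequence[CnvCall]) -> list[CnvCall]:
        return [
            c for c in own
            if not any(o.kind is c.kind
                       and _reciprocal_overlap(c, o) >= min_reciprocal_overlap
                       for o in other)
        ]
    return specific(a, b), specific(b, a)


@dataclass
class AnnotatedCnv:
    call: CnvCall
    coding: bool
    genes: frozenset = field(default_factory=frozenset)


def coding_overlap(cnvs: Iterable[CnvCall], gene_models: ExonModel) -> list[AnnotatedCnv]:
    """Label each CNV coding/non-coding with the exon-overlapped gene set."""
    annotated = []
    for call in cnvs:
        genes = gene_models.genes_overlapping(call.chrom, call.start, call.end)
        annotated.append(AnnotatedCnv(call=call, coding=bool(genes),
                                      genes=frozenset(genes)))
    return annotated


def coding_counts(annotated: Sequence[AnnotatedCnv]) -> pd.DataFrame:
    """Counts of coding CNVs by kind (duplications vs deletions)."""
    rows = []
    for kind in (CnvKind.DUP, CnvKind.DEL):
        n = sum(1 for a in annotated if a.coding and a.call.kind is kind)
        rows.append({"kind": kind.name, "coding_cnvs": n})
    rows.append({"kind": "TOTAL",
                 "coding_cnvs": sum(1 for a in annotated if a.coding)})
    return pd.DataFrame(rows)


def genelist_intersect(annotated: Sequence[AnnotatedCnv],
                       gene_list: Iterable[str]) -> list[AnnotatedCnv]:
    """CNVs overlapping any gene in a phenotype gene list.

    An empty result is a valid, reportable outcome (no CNV touches a listed
    gene).
    """
    listed = set(gene_list)
    if not listed:
        warnings.warn("empty gene list: intersection is trivially empty")
    return [a for a in annotated if a.genes & listed]
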