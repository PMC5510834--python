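"""Consequence-annotation collapse and non-synonymous classification.

A variant overlapping several transcripts receives several annotations; for
tallying and candidate selection each variant is collapsed to a single term
by a fixed severity precedence (most consequential first).  The vocabulary
is closed; VEP-style consequence strings are accepted through a synonym map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .types import ConsequenceRecord, Locus, VariantClass

# Precedence orders, most severe first.  A variant with no annotation at all
# is intergenic by definition.
SNV_ORDER: tuple[str, ...] = (
    "stop gain",
    "stop loss",
    "splice donor/acceptor site",
    "missense",
    "coding unknown",
    "within noncoding gene",
    "mature miRNA",
    "synonymous",
    "splice region variant",
    "5' UTR",
    "3' UTR",
    "upstream",
    "downstream",
    "intronic",
    "intergenic",
)

INDEL_ORDER: tuple[str, ...] = (
    "stop gain",
    "splice donor/acceptor site",
    "frameshift",
    "codon indel",
    "within noncoding gene",
    "mature miRNA",
    "splice region variant",
    "5' UTR",
    "3' UTR",
    "upstream",
    "downstream",
    "intronic",
    "intergenic",
)

# Ensembl-VEP consequence strings mapped onto the closed vocabulary above.
VEP_SYNONYMS: dict[str, str] = {
    "stop_gained": "stop gain",
    "stop_lost": "stop loss",
    "splice_donor_variant": "splice donor/acceptor site",
    "splice_acceptor_variant": "splice donor/acceptor site",
    "essential_splice_site": "splice donor/acceptor site",
    "missense_variant": "missense",
    "non_synonymous_coding": "missense",
    "coding_sequence_variant": "coding unknown",
    "coding_unknown": "coding unknown",
    "non_coding_transcript_variant": "within noncoding gene",
    "nc_transcript_variant": "within noncoding gene",
    "within_non_coding_gene": "within noncoding gene",
    "non_coding_transcript_exon_variant": "within noncoding gene",
    "mature_mirna_variant": "mature miRNA",
    "synonymous_variant": "synonymous",
    "synonymous_coding": "synonymous",
    "splice_region_variant": "splice region variant",
    "5_prime_utr_variant": "5' UTR",
    "3_prime_utr_variant": "3' UTR",
    "upstream_gene_variant": "upstream",
    "downstream_gene_variant": "downstream",
    "intron_variant": "intronic",
    "intergenic_variant": "intergenic",
    "frameshift_variant": "frameshift",
    "frameshift_coding": "frameshift",
    "inframe_insertion": "codon indel",
    "inframe_deletion": "codon indel",
    "complex_indel": "codon indel",
}


@dataclass(frozen=True)
class PrecedenceOrder:
    snv_order: tuple[str, ...] = SNV_ORDER
    indel_order: tuple[str, ...] = INDEL_ORDER

    def order_for(self, vclass: VariantClass) -> tuple[str, ...]:
        return self.snv_order if vclass is VariantClass.SNV else self.indel_order


@dataclass(frozen=True)
class NonSynDefinition:
    """Terms counted as non-synonymous (protein-altering) per variant class.

    For SNVs: missense, stop gain/loss and essential splice sites.  For
    indels additionally frameshifts and in-frame (codon) indels.
    """

    snv_terms: frozenset = frozenset(
        {"missense", "stop gain", "stop loss", "splice donor/acceptor site"})
    indel_terms: frozenset = frozenset(
        {"stop gain", "splice donor/acceptor site", "frameshift", "codon indel"})

    def terms_for(self, vclass: VariantClass) -> frozenset:
        return self.snv_terms if vclass is VariantClass.SNV else self.indel_terms


@dataclass(frozen=True)
class CollapsedAnnotation:
    term: str
    gene: str


def canonical_term(term: str, vclass: VariantClass) -> str:
    """Map a raw consequence string to the closed vocabulary; fatal if unknown."""
    t = term.strip()
    key = t.lower().replace(" ", "_").replace("'", "").replace("-", "_")
    vocab = SNV_ORDER if vclass is VariantClass.SNV else INDEL_ORDER
    if t.lower() in {v.lower() for v in vocab}:
        return next(v for v in vocab if v.lower() == t.lower())
    mapped = VEP_SYNONYMS.get(key) or VEP_SYNONYMS.get(t.lower())
    if mapped is None or mapped not in vocab:
        raise ValueError(
            f"unknown consequence term {term!r} for class {vclass.name}; "
            f"vocabulary: {vocab}")
    return mapped


def collapse_consequences(
    records: Iterable[ConsequenceRecord],
    order: Optional[PrecedenceOrder] = None,
    all_loci: Optional[Iterable[Locus]] = None,
) -> dict[Locus, CollapsedAnnotation]:
    """Collapse per-transcript annotations to one term per variant.

    Each locus maps to the highest-precedence term among its records; ties
    between transcripts of equal precedence attribute the gene of the first
    transcript in sorted order.  Loci in ``all_loci`` with no record at all
    collapse to intergenic.
    """
    order = order or PrecedenceOrder()
    per_locus: dict[Locus, list[tuple[int, str, str, str]]] = {}
    for rec in records:
        vocab = order.order_for(rec.locus.vclass)
        term = canonical_term(rec.term, rec.locus.vclass)
        rank = vocab.index(term)
        per_locus.setdefault(rec.locus, []).append(
            (rank, rec.transcript, term, rec.gene))
    collapsed: dict[Locus, CollapsedAnnotation] = {}
    for locus, entries in per_locus.items():
        entries.sort()  # by rank, then transcript id
        rank, _, term, gene = entries[0]
        collapsed[locus] = CollapsedAnnotation(term=term, gene=gene)
    if all_loci is not None:
        for locus in all_loci:
            collapsed.setdefault(locus, CollapsedAnnotation("intergenic", ""))
    return collapsed


def annotation_distribution(
    collapsed: dict[Locus, CollapsedAnnotation],
    vclass: VariantClass,
    order: Optional[PrecedenceOrder] = None,
) -> pd.DataFrame:
    """Tally collapsed terms for one variant class, with percentages of all.

    Term counts are conservative: they sum to the number of loci of the class.
    """
    order = order or PrecedenceOrder()
    vocab = order.order_for(vclass)
    counts = dict.fromkeys(vocab, 0)
    total = 0
    for locus, ann in collapsed.items():
        if locus.vclass is vclass:
            counts[ann.term] += 1
            total += 1
    rows = [
        {"annotation": term, "count": n,
         "pct_of_all": round(n / total * 100.0, 2) if total else 0.0}
        for term, n in counts.items()
    ]
    df = pd.DataFrame(rows)
    df.attrs["total"] = total
    return df


def select_nonsynonymous(
    collapsed: dict[Locus, CollapsedAnnotation],
    defn: Optional[NonSynDefinition] = None,
) -> set[Locus]:
    """Loci whose collapsed term is protein-altering for their class."""
    defn = defn or NonSynDefinition()
    return {
        locus for locus, ann in collapsed.items()
        if ann.term in defn.terms_for(locus.vclass)
    }
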