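"""Strain-specific variant identification between two inbred callsets.

A variant is *strain-specific* when it is called homozygous-alternate with
adequate evidence in one strain, is not called in the other strain, and the
other strain's data at that site are good enough to trust the absence.
Candidates where the other strain is under-covered are *omitted* rather than
counted — absence of evidence is not evidence of absence.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .types import (
    GenomeIntervals,
    StrainCallset,
    VariantCall,
    VariantClass,
    Zygosity,
)


class MatchKey(enum.Enum):
    """How "present in the other strain" is decided.

    POSITION_ALLELE: the other strain must carry the same alternate allele.
    POSITION_ONLY: any non-reference call at the same site counts as present.
    """

    POSITION_ALLELE = "position_allele"
    POSITION_ONLY = "position_only"


@dataclass
class StrainCompareParams:
    """Evidence thresholds for the comparison; boundaries are inclusive."""

    min_depth: int = 3
    min_qual: float = 30.0
    match_key: MatchKey = MatchKey.POSITION_ALLELE
    gap_intervals: Optional[GenomeIntervals] = None

    def __post_init__(self) -> None:
        if self.min_depth < 0 or self.min_qual < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class StrainSpecificSet:
    """Strain-specific variants of one strain plus comparison bookkeeping."""

    strain: str
    variants: list[VariantCall] = field(default_factory=list)
    omitted_low_evidence: int = 0
    gap_excluded_indels: int = 0
    n_contributing: dict[VariantClass, int] = field(default_factory=dict)
    n_homozygous: dict[VariantClass, int] = field(default_factory=dict)

    def specific_count(self, vclass: VariantClass) -> int:
        return sum(1 for v in self.variants if v.vclass == vclass)


def _meets_evidence(depth: int, qual: float, params: StrainCompareParams) -> bool:
    return depth >= params.min_depth and qual >= params.min_qual


def _present_in_other(call: VariantCall, other: StrainCallset,
                      match_key: MatchKey) -> bool:
    if match_key is MatchKey.POSITION_ALLELE:
        other_call = other.get(call.locus)
        candidates = [other_call] if other_call is not None else []
    else:
        candidates = other.calls_at(call.locus.chrom, call.locus.pos)
    # a HET or HOM_ALT call counts as presence; an explicit HOM_REF does not
    return any(c.zygosity in (Zygosity.HET, Zygosity.HOM_ALT) for c in candidates)


def _one_direction(own: StrainCallset, other: StrainCallset,
                   params: StrainCompareParams) -> StrainSpecificSet:
    result = StrainSpecificSet(strain=own.strain)
    counts = {VariantClass.SNV: 0, VariantClass.INDEL: 0}
    homs = {VariantClass.SNV: 0, VariantClass.INDEL: 0}
    for call in own:
        if not _meets_evidence(call.depth, call.qual, params):
            continue
        if (call.vclass is VariantClass.INDEL and params.gap_intervals is not None
                and params.gap_intervals.overlaps(call.locus.chrom, *call.locus.ref_span)):
            result.gap_excluded_indels += 1
            continue
        if call.zygosity is Zygosity.MISSING:
            continue
        counts[call.vclass] += 1
        if call.zygosity is not Zygosity.HOM_ALT:
            continue
        homs[call.vclass] += 1
        if _present_in_other(call, other, params.match_key):
            continue
        evidence = other.evidence_at(call.locus.chrom, call.locus.pos)
        if evidence is None or not _meets_evidence(*evidence, params):
            result.omitted_low_evidence += 1
            continue
        result.variants.append(call)
    result.n_contributing = counts
    result.n_homozygous = homs
    return result


def strain_specific_variants(
    a: StrainCallset,
    b: StrainCallset,
    params: Optional[StrainCompareParams] = None,
) -> tuple[StrainSpecificSet, StrainSpecificSet]:
    """Identify homozygous variants specific to each of two strains.

    A variant in strain ``a`` qualifies iff it is HOM_ALT with depth and QUAL
    at or above the thresholds, the matching variant (per ``match_key``) is
    absent from strain ``b``, and ``b``'s evidence at the site itself meets
    the thresholds; otherwise it is tallied under ``omitted_low_evidence``.
    Indels overlapping reference-gap intervals are excluded outright.
    The comparison is symmetric; both directions are returned.
    """
    params = params or StrainCompareParams()
    return _one_direction(a, b, params), _one_direction(b, a, params)


def tally_table(set_a: StrainSpecificSet, set_b: StrainSpecificSet) -> pd.DataFrame:
    """Per-strain, per-class variant tallies with the strain-specific percentage.

    The percentage is strain-specific / homozygous x 100, rounded to 2 decimals.
    """
    rows = []
    for sset in (set_a, set_b):
        for vclass in (VariantClass.SNV, VariantClass.INDEL):
            hom = sset.n_homozygous.get(vclass, 0)
            spec = sset.specific_count(vclass)
            rows.append({
                "strain": sset.strain,
                "variant_type": vclass.name,
                "variants": sset.n_contributing.get(vclass, 0),
                "homozygous": hom,
                "strain_specific": spec,
                "strain_specific_pct": specific_percentage(spec, hom),
            })
    return pd.DataFrame(rows)


def specific_percentage(specific: int, homozygous: int) -> float:
    """Strain-specific share of homozygous variants, in %, 2 decimals."""
    if homozygous == 0:
        return 0.0
    return round(specific / homozygous * 100.0, 2)
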