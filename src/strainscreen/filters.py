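"""The candidate-prioritization cascade: high-confidence evidence filter,
repeat exclusion for indels, panel privacy and frequency screens, and the
tiered report that tracks how many candidates each step retains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Optional, Sequence

import pandas as pd

from .types import GenomeIntervals, Locus, PanelCatalog, VariantCall, VariantClass


@dataclass
class ConfidenceParams:
    """Five-criterion evidence thresholds for high-confidence calls.

    All boundaries are inclusive: a call at exactly the threshold passes.
    ``min_alt_fraction`` uses total reads at the site as denominator.
    """

    min_depth: int = 10
    min_qual: float = 30.0
    min_mq: float = 40.0
    min_gq: float = 20.0
    min_alt_fraction: float = 0.80

    def __post_init__(self) -> None:
        if min(self.min_depth, self.min_qual, self.min_mq, self.min_gq) < 0:
            raise ValueError("thresholds must be non-negative")
        if not (0.0 <= self.min_alt_fraction <= 1.0):
            raise ValueError("min_alt_fraction must be in [0, 1]")

    def passes(self, call: VariantCall) -> bool:
        frac = call.alt_fraction
        return (
            call.depth >= self.min_depth
            and call.qual >= self.min_qual
            and call.mq >= self.min_mq
            and call.gq >= self.min_gq
            and frac is not None
            and frac >= self.min_alt_fraction
        )


def high_confidence_filter(
    variants: Iterable[VariantCall],
    params: Optional[ConfidenceParams] = None,
) -> list[VariantCall]:
    """Keep calls meeting every one of the five evidence criteria.

    A record claiming alt-supporting reads at zero total depth is malformed
    and is rejected with a warning.
    """
    params = params or ConfidenceParams()
    kept = []
    for call in variants:
        if call.depth == 0 and call.alt_reads > 0:
            warnings.warn(f"{call.locus}: alt_reads > 0 at depth 0, record rejected")
            continue
        if params.passes(call):
            kept.append(call)
    return kept


def repeat_filter(
    indels: Iterable[VariantCall],
    repeats: GenomeIntervals,
) -> list[VariantCall]:
    """Drop indels whose reference span overlaps any repeat-masked interval."""
    return [
        call for call in indels
        if not repeats.overlaps(call.locus.chrom, *call.locus.ref_span)
    ]


def privacy_screen(
    variants: Iterable[Locus],
    panels: Sequence[PanelCatalog],
) -> tuple[list[Locus], list[tuple[Locus, dict[str, int]]]]:
    """Split candidates into private (absent from every panel) and seen.

    Seen variants are returned with their per-panel presence counts.
    """
    private: list[Locus] = []
    seen: list[tuple[Locus, dict[str, int]]] = []
    for locus in variants:
        counts = {panel.name: panel.count(locus) for panel in panels}
        if all(c == 0 for c in counts.values()):
            private.append(locus)
        else:
            seen.append((locus, counts))
    return private, seen


def frequency_screen(
    variants: Iterable[Locus],
    panels: Sequence[PanelCatalog],
    thresholds: Mapping[str, int],
) -> list[Locus]:
    """Keep variants rarer than the per-panel threshold in EVERY panel.

    Thresholds are exclusive upper bounds on the presence count (a threshold
    of 4 keeps counts 0-3).  A variant absent from a panel has count 0.
    """
    for panel in panels:
        if panel.name not in thresholds:
            raise KeyError(f"no threshold supplied for panel {panel.name!r}")
    return [
        locus for locus in variants
        if all(panel.count(locus) < thresholds[panel.name] for panel in panels)
    ]


@dataclass
class CascadeTier:
    name: str
    count: int
    pct_of_first: float


def cascade_report(
    tier_sets: Sequence[tuple[str, Iterable[Hashable]]],
) -> pd.DataFrame:
    """Per-tier counts and percentages of the first (denominator) tier.

    Tiers must be nested — each a subset of the previous — otherwise the
    pipeline is mis-wired and the report refuses to continue.
    """
    if not tier_sets:
        raise ValueError("cascade_report needs at least one tier")
    materialized = [(name, set(members)) for name, members in tier_sets]
    for (prev_name, prev), (name, cur) in zip(materialized, materialized[1:]):
        if not cur <= prev:
            raise ValueError(
                f"tier {name!r} is not a subset of tier {prev_name!r}: "
                "cascade tiers must be nested")
    denom = len(materialized[0][1])
    rows = [
        {"tier": name, "count": len(members),
         "pct_of_first": round(len(members) / denom * 100.0, 2) if denom else 0.0}
        for name, members in materialized
    ]
    return pd.DataFrame(rows)


def split_by_class(
    variants: Iterable[VariantCall],
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Convenience split into (SNVs, indels)."""
    snvs, indels = [], []
    for call in variants:
        (snvs if call.vclass is VariantClass.SNV else indels).append(call)
    return snvs, indels
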