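"""Depth-threshold coverage summaries over autosomes versus the X chromosome.

Reference-gap (N-run) positions are excluded from every denominator: they
cannot be covered, so counting them would deflate every fraction.  Threshold
comparisons are inclusive (depth >= t).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .types import DepthTrack, norm_chrom

DEFAULT_THRESHOLDS = (1, 3, 5, 10, 15, 20)


@dataclass
class CoverageSummary:
    region: str  # "autosomal" or "X"
    average_depth: float
    fraction_at_least: dict[int, float]  # threshold -> fraction of non-gap bases
    n_bases: int  # non-gap denominator

    def percent_at_least(self, t: int) -> float:
        return round(self.fraction_at_least[t] * 100.0, 1)


def _summarize(tracks: Sequence[DepthTrack], region: str,
               thresholds: Sequence[int]) -> CoverageSummary:
    depth_sum = 0
    n_bases = 0
    counts = dict.fromkeys(thresholds, 0)
    for track in tracks:
        good = ~track.mask
        if not good.any():
            warnings.warn(f"chromosome {track.chrom} is fully masked, excluded")
            continue
        d = track.depths[good]
        depth_sum += int(d.sum())
        n_bases += int(good.sum())
        for t in thresholds:
            counts[t] += int(np.count_nonzero(d >= t))
    if n_bases == 0:
        raise ValueError(f"no unmasked bases in region {region!r}")
    return CoverageSummary(
        region=region,
        average_depth=depth_sum / n_bases,
        fraction_at_least={t: counts[t] / n_bases for t in thresholds},
        n_bases=n_bases,
    )


def coverage_summary(
    tracks: Sequence[DepthTrack],
    x_chrom: str = "X",
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
) -> tuple[CoverageSummary, CoverageSummary]:
    """Coverage summaries for (autosomes, X chromosome).

    Average depth is total depth over non-gap length; per-threshold fractions
    use inclusive >= semantics and are non-increasing in the threshold.
    """
    x_name = norm_chrom(x_chrom)
    autosomal = [t for t in tracks if t.chrom != x_name]
    x_tracks = [t for t in tracks if t.chrom == x_name]
    if not autosomal or not x_tracks:
        raise ValueError("need at least one autosomal and one X-chromosome track")
    return (_summarize(autosomal, "autosomal", thresholds),
            _summarize(x_tracks, "X", thresholds))


def coverage_table(summaries: Sequence[CoverageSummary],
                   strain: str = "") -> pd.DataFrame:
    """One row per region: average depth and % bases at each threshold."""
    rows = []
    for s in summaries:
        row = {"strain": strain, "region": s.region,
               "average_depth": round(s.average_depth, 2)}
        for t in sorted(s.fraction_at_least):
            row[f"pct_ge_{t}x"] = s.percent_at_least(t)
        rows.append(row)
    return pd.DataFrame(rows)
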