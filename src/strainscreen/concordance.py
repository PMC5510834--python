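"""Chip-versus-sequencing concordance QC.

An independent SNP genotyping array provides, per assayed site, whether the
strain is polymorphic against the reference.  Scoring the sequencing callset
against those assignments yields sensitivity (polymorphic sites detected)
and specificity (non-polymorphic sites confirmed), a false-positive /
false-negative decomposition, attribution of discordances to suspected
reference-assembly errors, and quality/depth profiles of the false
positives.

Detection is site-level: a chip-polymorphic SNP counts as detected when the
callset holds a qualifying non-reference call at that position, regardless
of which alternate allele — mirroring how array polymorphic/non-polymorphic
assignments are defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .types import ChipGenotype, StrainCallset, VariantCall, Zygosity


def _round2(x: float) -> float:
    return round(x, 2)


@dataclass
class ConcordanceResult:
    strain: str
    n_polymorphic: int = 0
    n_detected: int = 0
    n_nonpolymorphic: int = 0
    n_confirmed: int = 0
    n_excluded: int = 0
    fp_records: list[tuple[ChipGenotype, VariantCall]] = field(default_factory=list)
    fn_records: list[ChipGenotype] = field(default_factory=list)

    @property
    def sensitivity(self) -> float:
        if self.n_polymorphic == 0:
            return 0.0
        return _round2(self.n_detected / self.n_polymorphic * 100.0)

    @property
    def specificity(self) -> float:
        if self.n_nonpolymorphic == 0:
            return 0.0
        return _round2(self.n_confirmed / self.n_nonpolymorphic * 100.0)

    @property
    def fp_count(self) -> int:
        return self.n_nonpolymorphic - self.n_confirmed

    @property
    def fn_count(self) -> int:
        return self.n_polymorphic - self.n_detected


def chip_concordance(
    callset: StrainCallset,
    chip: Iterable[ChipGenotype],
    min_depth: int = 3,
    min_qual: float = 30.0,
    known_chroms: Optional[set[str]] = None,
) -> ConcordanceResult:
    """Score a sequencing callset against array polymorphic/non-polymorphic calls.

    A qualifying variant call has depth >= ``min_depth``, QUAL >= ``min_qual``
    and a non-reference genotype at the chip position.  Chip SNPs on
    chromosomes unknown to the callset (when ``known_chroms`` is given) are
    excluded with a warning and counted in ``n_excluded``.
    """
    result = ConcordanceResult(strain=callset.strain)
    for snp in chip:
        if known_chroms is not None and snp.chrom not in known_chroms:
            warnings.warn(f"chip SNP {snp.snp_id} on unknown chromosome {snp.chrom}, excluded")
            result.n_excluded += 1
            continue
        qualifying = [
            c for c in callset.calls_at(snp.chrom, snp.pos)
            if c.zygosity in (Zygosity.HET, Zygosity.HOM_ALT)
            and c.depth >= min_depth and c.qual >= min_qual
        ]
        if snp.array_call:
            result.n_polymorphic += 1
            if qualifying:
                result.n_detected += 1
            else:
                result.fn_records.append(snp)
        else:
            result.n_nonpolymorphic += 1
            if qualifying:
                best = max(qualifying, key=lambda c: (c.qual, c.depth))
                result.fp_records.append((snp, best))
            else:
                result.n_confirmed += 1
    return result


def refdisc_attribution(
    discordant: Sequence[ChipGenotype],
) -> tuple[int, float]:
    """Share of a discordant (FP or FN) set attributable to reference errors.

    A discordance is attributed to a suspect reference base when the array's
    own reference-strain allele disagrees with the assembly base at that
    position.  Returns (count, percentage of the set, 2 decimals); an empty
    set reports (0, 0.0).
    """
    discordant = list(discordant)
    if not discordant:
        return 0, 0.0
    n = sum(1 for snp in discordant if snp.reference_discordant)
    return n, _round2(n / len(discordant) * 100.0)


def fp_profile(
    fp_records: Sequence[tuple[ChipGenotype, VariantCall]],
) -> Optional[tuple[float, float]]:
    """Mean QUAL and mean depth of the false-positive calls (2 decimals).

    High mean quality at near-average depth among FPs points at systematic
    platform disagreement rather than marginal calls.  Empty set -> None.
    """
    if not fp_records:
        return None
    quals = [call.qual for _, call in fp_records]
    depths = [call.depth for _, call in fp_records]
    return _round2(sum(quals) / len(quals)), _round2(sum(depths) / len(depths))
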