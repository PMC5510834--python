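"""Co-segregation screening of candidate variants against extreme-phenotype
F2 animals, and clustering of survivors into genomic blocks.

The strict screen demands homozygous carriage in every case animal; the
permissive screen accepts any non-reference genotype ("irrespective of
zygosity").  Both demand complete absence of the alternate allele from every
control animal.  Strict survivors are therefore always a subset of
permissive survivors on the same inputs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .filters import frequency_screen
from .types import F2Cohort, Locus, PanelCatalog, Phenotype, Zygosity

_CARRIER = (Zygosity.HET, Zygosity.HOM_ALT)


class ScreenMode(enum.Enum):
    STRICT = "strict"
    PERMISSIVE = "permissive"


@dataclass(frozen=True)
class BlockReport:
    """Minimal interval covering all survivors on one chromosome.

    ``span_bp`` is end - start on 1-based inclusive coordinates (the distance
    between the outermost members, not the base count).
    """

    chrom: str
    start_pos: int
    end_pos: int
    members: tuple[Locus, ...]
    n_total: int

    @property
    def span_bp(self) -> int:
        return self.end_pos - self.start_pos

    @property
    def span_mbp(self) -> float:
        return round(self.span_bp / 1e6, 1)

    @property
    def n_inside(self) -> int:
        return len(self.members)


def segregation_screen(
    candidates: Iterable[Locus],
    cohort: F2Cohort,
    case_phenotype: Phenotype,
    mode: ScreenMode = ScreenMode.STRICT,
    missing_control_fails: bool = True,
) -> set[Locus]:
    """Candidates whose genotypes co-segregate with the case phenotype.

    STRICT keeps loci homozygous-alternate in every case animal; PERMISSIVE
    keeps loci with at least one alternate allele in every case animal.  In
    both modes no control animal may carry the alternate allele.  A MISSING
    genotype in a case fails the candidate (presence unproven); MISSING in a
    control fails it too by default (absence unproven), relaxable via
    ``missing_control_fails``.
    """
    cases = cohort.with_phenotype(case_phenotype)
    controls = [a for a in cohort.animals if a.phenotype != case_phenotype]
    if not cases or not controls:
        raise ValueError(
            "segregation screen needs at least one case and one control animal")
    required = (Zygosity.HOM_ALT,) if mode is ScreenMode.STRICT else _CARRIER
    survivors: set[Locus] = set()
    for locus in candidates:
        if not all(a.genotype(locus) in required for a in cases):
            continue
        ok = True
        for a in controls:
            g = a.genotype(locus)
            if g in _CARRIER or (g is Zygosity.MISSING and missing_control_fails):
                ok = False
                break
        if ok:
            survivors.add(locus)
    return survivors


def combined_screen(
    candidates: Iterable[Locus],
    cohort: F2Cohort,
    case_phenotype: Phenotype,
    panels: Sequence[PanelCatalog],
    thresholds: Mapping[str, int],
    mode: ScreenMode = ScreenMode.STRICT,
    gene_map: Optional[Mapping[Locus, str]] = None,
    strain: str = "",
) -> pd.DataFrame:
    """Intersect segregation survivors with the panel frequency screen.

    The report carries, per surviving variant: strain, gene (when a gene map
    is supplied), the chrom:posRef>Alt locus string, and the presence tally
    in each panel.
    """
    candidates = list(candidates)
    segregating = segregation_screen(candidates, cohort, case_phenotype, mode)
    rare = set(frequency_screen(candidates, panels, thresholds))
    survivors = sorted(segregating & rare, key=lambda l: l.sort_key())
    rows = []
    for locus in survivors:
        row = {
            "strain": strain,
            "gene": (gene_map or {}).get(locus, ""),
            "chrom": locus.chrom,
            "pos": locus.pos,
            "ref": locus.ref,
            "alt": locus.alt,
            "variant": str(locus),
        }
        for panel in panels:
            row[f"{panel.name}_count"] = panel.count(locus)
            row[f"{panel.name}_n"] = panel.n_strains
        rows.append(row)
    columns = ["strain", "gene", "chrom", "pos", "ref", "alt", "variant"] + [
        col for panel in panels for col in (f"{panel.name}_count", f"{panel.name}_n")]
    return pd.DataFrame(rows, columns=columns)


def block_scan(survivors: Iterable[Locus]) -> list[BlockReport]:
    """Per-chromosome minimal blocks covering the screen survivors.

    Each report notes how many of ALL survivors fall inside its block, so a
    single chromosome hoarding most survivors is immediately visible.
    """
    survivors = list(survivors)
    if not survivors:
        raise ValueError("block_scan needs at least one survivor")
    by_chrom: dict[str, list[Locus]] = {}
    for locus in survivors:
        by_chrom.setdefault(locus.chrom, []).append(locus)
    reports = []
    for chrom in sorted(by_chrom):
        members = tuple(sorted(by_chrom[chrom], key=lambda l: l.sort_key()))
        positions = [l.pos for l in members]
        reports.append(BlockReport(
            chrom=chrom,
            start_pos=min(positions),
            end_pos=max(positions),
            members=members,
            n_total=len(survivors),
        ))
    return reports
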