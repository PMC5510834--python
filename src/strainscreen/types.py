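"""Domain types shared by every stage of the prioritization cascade.

The central identity object is :class:`Locus` — one biallelic variant site
against the reference assembly.  Loci are normalized on construction
(chromosome-name dialect stripping, indel left-alignment/trimming) so that
the same physical event read from different sources (per-strain VCFs, panel
catalogs, candidate tables) compares equal.

Coordinates are 1-based throughout the variant-facing API; interval inputs
in BED convention (0-based half-open) are converted on read.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np
from intervaltree import IntervalTree

ALLELE_ALPHABET = frozenset("ACGT")


def norm_chrom(chrom: str) -> str:
    """Normalize chromosome-name dialects: 'chr7' and '7' name the same molecule."""
    c = str(chrom).strip()
    return c[3:] if c.lower().startswith("chr") else c


class Zygosity(enum.Enum):
    HOM_ALT = "hom_alt"
    HET = "het"
    HOM_REF = "hom_ref"
    MISSING = "missing"


class VariantClass(enum.Enum):
    SNV = "snv"
    INDEL = "indel"


class CnvKind(enum.Enum):
    DEL = "del"
    DUP = "dup"


class Phenotype(enum.Enum):
    HIGH_SEIZING = "high_seizing"
    NON_SEIZING = "non_seizing"


@dataclass(frozen=True)
class Locus:
    """A biallelic variant site: chromosome, 1-based position, ref and alt allele.

    Construction normalizes the representation so that equality is a usable
    identity key across data sources:

    * the chromosome name is stripped of a leading ``chr``;
    * shared trailing bases, then shared leading bases, of ref/alt are trimmed
      (left alignment for indels), bumping ``pos`` for each leading base removed;
    * alleles must be non-empty strings over {A, C, G, T} and must differ.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        chrom = norm_chrom(self.chrom)
        pos = int(self.pos)
        ref = str(self.ref).upper()
        alt = str(self.alt).upper()
        if not ref or not alt:
            raise ValueError("ref and alt alleles must be non-empty")
        # trim shared trailing bases, then shared leading bases (left-align)
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
        if pos < 1:
            raise ValueError(f"position must be >= 1, got {pos}")
        if ref == alt:
            raise ValueError(f"ref and alt are identical after normalization: {ref}")
        bad = (set(ref) | set(alt)) - ALLELE_ALPHABET
        if bad:
            raise ValueError(f"non-ACGT characters in alleles: {sorted(bad)}")
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "pos", pos)
        object.__setattr__(self, "ref", ref)
        object.__setattr__(self, "alt", alt)

    @property
    def vclass(self) -> VariantClass:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return VariantClass.SNV
        return VariantClass.INDEL

    @property
    def ref_span(self) -> tuple[int, int]:
        """0-based half-open interval covered by the reference allele."""
        return self.pos - 1, self.pos - 1 + len(self.ref)

    def sort_key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class VariantCall:
    """One variant observation in one sample, with its genotype and evidence.

    ``depth`` is total reads at the site (the "x-fold coverage" quantity),
    ``qual`` the consensus quality, ``mq`` the mapping quality and ``gq`` the
    genotype quality, all on the PHRED scale.  ``alt_reads`` counts reads
    supporting the alternate allele.
    """

    locus: Locus
    zygosity: Zygosity
    depth: int = 0
    qual: float = 0.0
    mq: float = 0.0
    gq: float = 0.0
    alt_reads: int = 0

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not (0 <= self.alt_reads <= max(self.depth, self.alt_reads)):
            raise ValueError("alt_reads must be non-negative")

    @property
    def alt_fraction(self) -> Optional[float]:
        """Fraction of total reads supporting the alt allele; None at depth 0."""
        if self.depth <= 0:
            return None
        return self.alt_reads / self.depth

    @property
    def vclass(self) -> VariantClass:
        return self.locus.vclass


class StrainCallset:
    """All variant calls of one strain against the reference, keyed by locus.

    Besides the call map, the callset answers coverage queries at sites where
    no variant was called (``evidence_at``), which the strain-specific
    comparison needs to decide whether "absent in the other strain" is backed
    by adequate data or is merely a no-data site.
    """

    def __init__(self, strain: str, calls: Iterable[VariantCall] = (),
                 coverage: Optional[dict[tuple[str, int], tuple[int, float]]] = None):
        self.strain = strain
        self.calls: dict[Locus, VariantCall] = {}
        self._by_pos: dict[tuple[str, int], list[Locus]] = {}
        self.coverage: dict[tuple[str, int], tuple[int, float]] = {}
        if coverage:
            for (chrom, pos), dq in coverage.items():
                self.coverage[(norm_chrom(chrom), int(pos))] = (int(dq[0]), float(dq[1]))
        for call in calls:
            self.add(call)

    def add(self, call: VariantCall) -> None:
        if call.locus in self.calls:
            raise ValueError(f"duplicate call at {call.locus}")
        self.calls[call.locus] = call
        self._by_pos.setdefault((call.locus.chrom, call.locus.pos), []).append(call.locus)

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[VariantCall]:
        return iter(self.calls.values())

    def get(self, locus: Locus) -> Optional[VariantCall]:
        return self.calls.get(locus)

    def calls_at(self, chrom: str, pos: int) -> list[VariantCall]:
        """All calls at a (chrom, 1-based pos) site, any allele."""
        keys = self._by_pos.get((norm_chrom(chrom), int(pos)), [])
        return [self.calls[k] for k in keys]

    def set_coverage(self, chrom: str, pos: int, depth: int, qual: float) -> None:
        self.coverage[(norm_chrom(chrom), int(pos))] = (int(depth), float(qual))

    def evidence_at(self, chrom: str, pos: int) -> Optional[tuple[int, float]]:
        """(depth, qual) evidence at a site: from a call if present, else from
        the coverage track; None when the strain has no data there."""
        calls = self.calls_at(chrom, pos)
        if calls:
            best = max(calls, key=lambda c: (c.depth, c.qual))
            return best.depth, best.qual
        return self.coverage.get((norm_chrom(chrom), int(pos)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StrainCallset):
            return NotImplemented
        return (self.strain == other.strain and self.calls == other.calls)


@dataclass(frozen=True)
class ConsequenceRecord:
    """One variant-transcript consequence annotation."""

    locus: Locus
    transcript: str
    term: str
    gene: str


class PanelCatalog:
    """Presence tallies of variants across a named panel of external strains.

    Loci absent from the catalog have an implicit count of 0 (never observed
    in any panel strain).
    """

    def __init__(self, name: str, n_strains: int,
                 presence: Optional[dict[Locus, int]] = None):
        if n_strains <= 0:
            raise ValueError("panel must contain at least one strain")
        self.name = name
        self.n_strains = int(n_strains)
        self.presence: dict[Locus, int] = {}
        for locus, count in (presence or {}).items():
            self.set_count(locus, count)

    def set_count(self, locus: Locus, count: int) -> None:
        count = int(count)
        if not (0 <= count <= self.n_strains):
            raise ValueError(
                f"count {count} outside [0, {self.n_strains}] for panel {self.name}")
        self.presence[locus] = count

    def count(self, locus: Locus) -> int:
        return self.presence.get(locus, 0)

    def __len__(self) -> int:
        return len(self.presence)


@dataclass(frozen=True)
class CnvCall:
    """An interval-level copy-number event called in one strain.

    ``interval`` is (chrom, start, end), 0-based half-open.  ``fold`` is the
    copy-number ratio relative to the reference; 0 denotes complete loss and
    is permitted only for deletions.
    """

    strain: str
    chrom: str
    start: int
    end: int
    kind: CnvKind
    fold: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", norm_chrom(self.chrom))
        if self.end <= self.start:
            raise ValueError(f"CNV interval must satisfy end > start: {self}")
        if self.fold < 0:
            raise ValueError(f"negative fold-change: {self.fold}")
        if self.fold == 0 and self.kind is not CnvKind.DEL:
            raise ValueError("fold 0 (complete loss) is only valid for deletions")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ChipGenotype:
    """One array SNP assay: is the strain polymorphic versus the reference?

    ``array_bn_allele`` is the allele the array assigns to the reference
    strain; disagreement with ``reference_allele`` (the assembly base) marks
    sites where the assembly itself is suspect.
    """

    snp_id: str
    chrom: str
    pos: int
    reference_allele: str
    array_bn_allele: str
    array_call: bool  # True = array says polymorphic vs reference

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", norm_chrom(self.chrom))

    @property
    def reference_discordant(self) -> bool:
        return self.array_bn_allele.upper() != self.reference_allele.upper()


@dataclass
class F2Animal:
    """A second-generation cross animal with phenotype label and genotypes."""

    animal_id: str
    phenotype: Phenotype
    genotypes: dict[Locus, Zygosity] = field(default_factory=dict)

    def genotype(self, locus: Locus) -> Zygosity:
        return self.genotypes.get(locus, Zygosity.MISSING)


@dataclass
class F2Cohort:
    animals: list[F2Animal]

    def with_phenotype(self, phenotype: Phenotype) -> list[F2Animal]:
        return [a for a in self.animals if a.phenotype == phenotype]

    def __len__(self) -> int:
        return len(self.animals)


@dataclass
class DepthTrack:
    """Per-base read depth along one chromosome, with a reference-gap mask.

    Masked (gap / N) positions are excluded from every coverage denominator.
    """

    chrom: str
    depths: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = norm_chrom(self.chrom)
        self.depths = np.asarray(self.depths, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.depths.shape != self.mask.shape:
            raise ValueError("depths and mask must have equal length")


class GenomeIntervals:
    """A merged, queryable collection of genomic intervals (BED semantics).

    Intervals are stored 0-based half-open per chromosome; membership queries
    take 1-based positions to match the variant-facing API.
    """

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}

    def add(self, chrom: str, start: int, end: int) -> None:
        if end <= start:
            raise ValueError(f"interval must satisfy start < end: [{start}, {end})")
        self._trees.setdefault(norm_chrom(chrom), IntervalTree()).addi(start, end)

    def merge(self) -> "GenomeIntervals":
        for tree in self._trees.values():
            tree.merge_overlaps(strict=False)
        return self

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        tree = self._trees.get(norm_chrom(chrom))
        return bool(tree is not None and tree.overlaps_point(pos - 1))

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """Overlap with a 0-based half-open interval."""
        tree = self._trees.get(norm_chrom(chrom))
        return bool(tree is not None and tree.overlap(start, end))

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        tree = self._trees.get(norm_chrom(chrom))
        if tree is None:
            return []
        return sorted((iv.begin, iv.end) for iv in tree)

    def chroms(self) -> list[str]:
        return sorted(self._trees)

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())


class ExonModel:
    """Exon intervals tagged with gene identifiers, for CNV coding overlap."""

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}

    def add_exon(self, chrom: str, start: int, end: int, gene: str) -> None:
        if end <= start:
            raise ValueError("exon must satisfy start < end")
        self._trees.setdefault(norm_chrom(chrom), IntervalTree()).addi(start, end, gene)

    def genes_overlapping(self, chrom: str, start: int, end: int) -> set[str]:
        tree = self._trees.get(norm_chrom(chrom))
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}
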