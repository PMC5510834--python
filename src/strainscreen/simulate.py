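"""Synthetic two-strain + F2-cross data generator with known ground truth.

The generator emulates the inputs of a two-inbred-strain variant
prioritization study: two fully homozygous strains diverged from a shared
reference, external strain panels (28 and 40 strains), an independent SNP
genotyping chip, an F1 x F1 intercross with recombination and a planted
causal variant driving a seizure phenotype, CNV calls, and per-base depth
tracks.  Every output is paired with a truth table so each pipeline stage
can be tested against exact expectations.

All randomness flows from ``SimConfig.seed`` through independent
``numpy.random.Generator`` streams per stage; the same config always yields
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import (
    write_chip_tsv,
    write_cnv_tsv,
    write_f2_cohort,
    write_panel_tsv,
    write_strain_vcf,
)
from .types import (
    ChipGenotype,
    CnvCall,
    CnvKind,
    ConsequenceRecord,
    DepthTrack,
    F2Animal,
    F2Cohort,
    Locus,
    PanelCatalog,
    Phenotype,
    StrainCallset,
    VariantCall,
    Zygosity,
)

_BASES = np.array(list("ACGT"))

# high-confidence evidence thresholds the quality model is anchored on
_HC = {"depth": 10, "qual": 30.0, "mq": 40.0, "gq": 20.0, "alt_fraction": 0.80}


@dataclass
class QualityModel:
    """Evidence-field distributions for true variant calls.

    Defaults are anchored on a short-read whole-genome profile of ~15x mean
    depth and consensus qualities around 58.  ``hc_fail_fraction`` of true
    calls are drawn to fail exactly one of the five high-confidence criteria
    (which criterion is chosen uniformly), emulating the attrition real calls
    show at stringent thresholds.
    """

    depth_mean: float = 15.0
    qual_mean: float = 58.0
    qual_sd: float = 10.0
    mq_mean: float = 55.0
    mq_sd: float = 5.0
    gq_mean: float = 70.0
    gq_sd: float = 15.0
    hc_fail_fraction: float = 0.35


@dataclass
class ChipConfig:
    n_snps: int = 2000
    polymorphic_fraction: float = 0.5
    array_error_rate: float = 0.0
    reference_error_rate: float = 0.0
    strain: str = "A"  # which strain the chip assays


@dataclass
class CrossConfig:
    n_f2: int = 200
    crossovers_per_chrom_mean: float = 1.0
    penetrance: float = 1.0  # P(high-seizing | homozygous causal)


@dataclass
class CnvSimConfig:
    n_shared: int = 10
    n_a_specific: int = 20
    n_b_specific: int = 20
    n_unqualified: int = 10  # planted calls failing length/fold rules
    min_length: int = 5000
    max_length: int = 15000


@dataclass
class SimConfig:
    """Complete study design for one synthetic two-strain experiment."""

    seed: int = 0
    genome: tuple[tuple[str, int], ...] = (
        ("1", 400_000), ("2", 400_000), ("3", 400_000),
        ("4", 400_000), ("X", 400_000),
    )
    n_shared: int = 1500
    n_a_specific: int = 1000
    n_b_specific: int = 1000
    indel_fraction: float = 0.2
    fraction_private: float = 0.3
    nonsyn_fraction: float = 0.02
    low_coverage_fraction: float = 0.05  # other-strain sites with depth < 3
    panel_sizes: tuple[int, int] = (28, 40)
    panel_p: float = 0.08  # per-strain carriage probability for panel-seen loci
    quality: QualityModel = field(default_factory=QualityModel)
    chip: ChipConfig = field(default_factory=ChipConfig)
    cross: CrossConfig = field(default_factory=CrossConfig)
    cnv: CnvSimConfig = field(default_factory=CnvSimConfig)
    cnv_truth: tuple[CnvCall, ...] = ()
    plant_causal: bool = True

    def __post_init__(self) -> None:
        for name in ("n_shared", "n_a_specific", "n_b_specific"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("indel_fraction", "fraction_private", "nonsyn_fraction",
                     "low_coverage_fraction"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if not any(c != "X" for c, _ in self.genome):
            raise ValueError("genome needs at least one autosome")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "genome" in d:
            d["genome"] = tuple((str(c), int(l)) for c, l in d["genome"])
        for key, sub in (("quality", QualityModel), ("chip", ChipConfig),
                         ("cross", CrossConfig), ("cnv", CnvSimConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class StrainSimulation:
    """Everything simulate_strains produced, plus the ground truth."""

    config: SimConfig
    reference: dict[str, str]
    callset_a: StrainCallset
    callset_b: StrainCallset
    truth: pd.DataFrame  # chrom,pos,ref,alt,category,private,nonsyn,causal,other_low_coverage
    consequences: list[ConsequenceRecord]

    @property
    def causal_locus(self) -> Optional[Locus]:
        rows = self.truth[self.truth["causal"]]
        if rows.empty:
            return None
        r = rows.iloc[0]
        return Locus(r["chrom"], int(r["pos"]), r["ref"], r["alt"])

    def loci(self, category: Optional[str] = None,
             private: Optional[bool] = None) -> list[Locus]:
        df = self.truth
        if category is not None:
            df = df[df["category"] == category]
        if private is not None:
            df = df[df["private"] == private]
        return [Locus(r.chrom, int(r.pos), r.ref, r.alt)
                for r in df.itertuples(index=False)]


def _draw_passing(rng: np.random.Generator, q: QualityModel) -> dict:
    """Evidence fields guaranteed to satisfy all five high-confidence criteria."""
    depth = max(_HC["depth"], int(rng.poisson(q.depth_mean)))
    return {
        "depth": depth,
        "qual": round(max(_HC["qual"], rng.normal(q.qual_mean, q.qual_sd)), 2),
        "mq": round(max(_HC["mq"], rng.normal(q.mq_mean, q.mq_sd)), 2),
        "gq": float(int(max(_HC["gq"], rng.normal(q.gq_mean, q.gq_sd)))),
        "alt_reads": max(int(np.ceil(_HC["alt_fraction"] * depth)),
                         int(rng.binomial(depth, 0.97))),
    }


def _draw_failing_one(rng: np.random.Generator, q: QualityModel) -> dict:
    fields = _draw_passing(rng, q)
    which = rng.integers(5)
    if which == 0:
        fields["depth"] = int(rng.integers(3, _HC["depth"]))  # still >= 3
        fields["alt_reads"] = fields["depth"]
    elif which == 1:
        fields["qual"] = round(float(rng.uniform(5.0, _HC["qual"] - 1.0)), 2)
    elif which == 2:
        fields["mq"] = round(float(rng.uniform(10.0, _HC["mq"] - 1.0)), 2)
    elif which == 3:
        fields["gq"] = float(int(rng.uniform(1.0, _HC["gq"] - 1.0)))
    else:
        fields["alt_reads"] = int(np.floor(0.79 * fields["depth"]))
    return fields


def _sample_positions(rng: np.random.Generator, genome, n_total: int,
                      spacing: int = 12) -> list[tuple[str, int]]:
    """Distinct, well-separated 1-based positions across the genome."""
    lengths = np.array([l for _, l in genome], dtype=float)
    capacity = int((lengths.sum()) / spacing * 0.8)
    if n_total > capacity:
        raise ValueError(
            f"requested {n_total} variants exceeds genome capacity "
            f"(~{capacity} at {spacing} bp spacing); enlarge the genome or "
            "reduce the counts")
    per_chrom = rng.multinomial(n_total, lengths / lengths.sum())
    out: list[tuple[str, int]] = []
    for (chrom, length), k in zip(genome, per_chrom):
        if k == 0:
            continue
        # oversample, dedupe, keep spaced (never materializes the full
        # position range, so large chromosomes stay cheap)
        cand = np.unique(rng.integers(
            spacing, length - spacing,
            size=min(6 * k + 32, max(length // spacing, 1))))
        kept: list[int] = []
        last = -spacing
        for p in cand:
            if p - last >= spacing:
                kept.append(int(p))
                last = p
            if len(kept) == k:
                break
        if len(kept) < k:
            raise ValueError(f"chromosome {chrom} too small for {k} spaced variants")
        out.extend((chrom, p) for p in kept)
    return out


def simulate_strains(cfg: SimConfig) -> StrainSimulation:
    """Generate the reference, both inbred callsets and the truth table.

    Inbred strains carry every true variant as HOM_ALT.  Shared variants
    appear in both callsets; specific variants appear in exactly one, while
    the other strain receives a coverage entry at the site — adequately
    covered except for a ``low_coverage_fraction`` of sites given depth < 3
    to exercise the omission rule.  Per-transcript consequence annotations
    (non-synonymous for a ``nonsyn_fraction`` of loci) are emitted alongside.
    """
    rng = np.random.default_rng(cfg.seed)
    reference = {
        chrom: "".join(rng.choice(_BASES, size=length))
        for chrom, length in cfg.genome
    }
    n_total = cfg.n_shared + cfg.n_a_specific + cfg.n_b_specific
    sites = _sample_positions(rng, cfg.genome, n_total)
    categories = (["shared"] * cfg.n_shared + ["A"] * cfg.n_a_specific
                  + ["B"] * cfg.n_b_specific)
    rng.shuffle(categories)

    callset_a = StrainCallset("A")
    callset_b = StrainCallset("B")
    truth_rows = []
    consequences: list[ConsequenceRecord] = []
    causal_planted = False
    q = cfg.quality

    for (chrom, pos), category in zip(sites, categories):
        seq = reference[chrom]
        is_indel = rng.random() < cfg.indel_fraction
        anchor = seq[pos - 1]
        if not is_indel:
            ref = anchor
            alt = str(rng.choice([b for b in "ACGT" if b != anchor]))
        else:
            ilen = int(rng.integers(1, 6))
            if rng.random() < 0.5:  # deletion
                ref = seq[pos - 1: pos + ilen]
                alt = anchor
            else:  # insertion
                ref = anchor
                alt = anchor + "".join(rng.choice(_BASES, size=ilen))
        locus = Locus(chrom, pos, ref, alt)
        private = (category != "shared") and (rng.random() < cfg.fraction_private)
        nonsyn = rng.random() < cfg.nonsyn_fraction
        causal = False
        if (cfg.plant_causal and not causal_planted and category == "A"
                and chrom != "X" and not is_indel):
            causal, private, nonsyn = True, True, True
            causal_planted = True

        def make_call() -> dict:
            if rng.random() < q.hc_fail_fraction:
                return _draw_failing_one(rng, q)
            return _draw_passing(rng, q)

        other_low = False
        if category in ("shared", "A"):
            callset_a.add(VariantCall(locus, Zygosity.HOM_ALT, **make_call()))
        if category in ("shared", "B"):
            callset_b.add(VariantCall(locus, Zygosity.HOM_ALT, **make_call()))
        if category in ("A", "B"):
            other = callset_b if category == "A" else callset_a
            if rng.random() < cfg.low_coverage_fraction:
                other_low = True
                other.set_coverage(chrom, pos, int(rng.integers(0, 3)),
                                   float(rng.uniform(0, 60)))
            else:
                other.set_coverage(chrom, pos,
                                   max(3, int(rng.poisson(q.depth_mean))),
                                   max(30.0, float(rng.normal(q.qual_mean, q.qual_sd))))

        gene = f"GENE{pos // 20000:02d}_{chrom}"
        if nonsyn:
            term = "missense" if not is_indel else "frameshift"
            consequences.append(ConsequenceRecord(locus, f"TX_{locus}", term, gene))
            # a second, milder transcript annotation to exercise the collapse
            consequences.append(ConsequenceRecord(locus, f"TXb_{locus}", "intronic", gene))
        else:
            term = str(rng.choice(["synonymous", "intronic", "intergenic", "upstream"])
                       ) if not is_indel else str(
                rng.choice(["intronic", "intergenic", "downstream"]))
            consequences.append(ConsequenceRecord(locus, f"TX_{locus}", term, gene))

        truth_rows.append({
            "chrom": locus.chrom, "pos": locus.pos, "ref": locus.ref,
            "alt": locus.alt, "vclass": locus.vclass.name, "category": category,
            "private": private, "nonsyn": nonsyn, "causal": causal,
            "other_low_coverage": other_low, "gene": gene,
        })

    truth = pd.DataFrame(truth_rows, columns=[
        "chrom", "pos", "ref", "alt", "vclass", "category", "private",
        "nonsyn", "causal", "other_low_coverage", "gene"])
    return StrainSimulation(cfg, reference, callset_a, callset_b, truth, consequences)


def simulate_panels(cfg: SimConfig,
                    truth: pd.DataFrame) -> tuple[PanelCatalog, PanelCatalog]:
    """External strain panels with presence counts for non-private loci.

    Private loci have count 0 in every panel.  Panel-seen specific loci draw
    counts as 1 + Binomial(n_strains - 1, panel_p), guaranteeing at least one
    carrier and never exceeding the panel size.
    """
    rng = np.random.default_rng(cfg.seed + 101)
    panels = [PanelCatalog(f"panel{n}", n) for n in cfg.panel_sizes]
    specific = truth[truth["category"].isin(["A", "B"])]
    for row in specific.itertuples(index=False):
        locus = Locus(row.chrom, int(row.pos), row.ref, row.alt)
        for panel in panels:
            if row.private:
                panel.set_count(locus, 0)
            else:
                panel.set_count(
                    locus, 1 + int(rng.binomial(panel.n_strains - 1, cfg.panel_p)))
    return panels[0], panels[1]


def simulate_chip(cfg: SimConfig, sim: StrainSimulation,
                  ) -> tuple[list[ChipGenotype], dict]:
    """Array genotypes for one strain plus the expected confusion table.

    Truly polymorphic chip sites are placed on SNVs the assayed strain
    carries; truly non-polymorphic sites on invariant reference positions.
    The array's polymorphic flag is flipped with ``array_error_rate``, and a
    ``reference_error_rate`` fraction of SNPs get an array reference-strain
    allele disagreeing with the assembly base (the suspect-reference
    mechanism).  The expected TP/FP/TN/FN are computed from the generated
    records and the callset's qualifying calls (depth >= 3, QUAL >= 30).
    """
    rng = np.random.default_rng(cfg.seed + 202)
    chipcfg = cfg.chip
    callset = sim.callset_a if chipcfg.strain == "A" else sim.callset_b
    carried = sim.truth[
        sim.truth["category"].isin(["shared", chipcfg.strain])
        & (sim.truth["vclass"] == "SNV")]
    n_poly = min(int(round(chipcfg.n_snps * chipcfg.polymorphic_fraction)),
                 len(carried))
    poly_rows = carried.sample(n=n_poly, random_state=int(rng.integers(2**31)))

    taken = {(r.chrom, int(r.pos)) for r in sim.truth.itertuples(index=False)}
    invariant_sites: list[tuple[str, int]] = []
    n_nonpoly = chipcfg.n_snps - n_poly
    while len(invariant_sites) < n_nonpoly:
        chrom, length = cfg.genome[int(rng.integers(len(cfg.genome)))]
        pos = int(rng.integers(10, length - 10))
        if (chrom, pos) not in taken:
            taken.add((chrom, pos))
            invariant_sites.append((chrom, pos))

    records: list[ChipGenotype] = []
    idx = 0
    truth_flags: list[bool] = []
    for row in poly_rows.itertuples(index=False):
        records.append(_chip_record(rng, chipcfg, idx, row.chrom, int(row.pos),
                                    sim.reference, truly_poly=True))
        truth_flags.append(True)
        idx += 1
    for chrom, pos in invariant_sites:
        records.append(_chip_record(rng, chipcfg, idx, chrom, pos,
                                    sim.reference, truly_poly=False))
        truth_flags.append(False)
        idx += 1

    expected = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
    for rec, truly_poly in zip(records, truth_flags):
        detected = any(
            c.zygosity in (Zygosity.HET, Zygosity.HOM_ALT)
            and c.depth >= 3 and c.qual >= 30.0
            for c in callset.calls_at(rec.chrom, rec.pos))
        if rec.array_call:
            expected["tp" if detected else "fn"] += 1
        else:
            expected["fp" if detected else "tn"] += 1
    n_poly_flagged = expected["tp"] + expected["fn"]
    n_nonpoly_flagged = expected["tn"] + expected["fp"]
    expected["sensitivity"] = round(
        expected["tp"] / n_poly_flagged * 100.0, 2) if n_poly_flagged else 0.0
    expected["specificity"] = round(
        expected["tn"] / n_nonpoly_flagged * 100.0, 2) if n_nonpoly_flagged else 0.0
    return records, expected


def _chip_record(rng, chipcfg: ChipConfig, idx: int, chrom: str, pos: int,
                 reference: dict[str, str], truly_poly: bool) -> ChipGenotype:
    ref_base = reference[chrom][pos - 1]
    if rng.random() < chipcfg.reference_error_rate:
        bn_allele = str(rng.choice([b for b in "ACGT" if b != ref_base]))
    else:
        bn_allele = ref_base
    array_call = truly_poly
    if rng.random() < chipcfg.array_error_rate:
        array_call = not array_call
    return ChipGenotype(
        snp_id=f"SNP{idx:06d}", chrom=chrom, pos=pos,
        reference_allele=ref_base, array_bn_allele=bn_allele,
        array_call=array_call)


def simulate_f2(cfg: SimConfig, sim: StrainSimulation,
                loci: Optional[Sequence[Locus]] = None) -> F2Cohort:
    """An F2 cohort from an F1 x F1 intercross of the two inbred strains.

    Both F1 parents are obligate heterozygotes at every strain-discriminating
    locus (one strain-A haplotype, one strain-B haplotype).  Each gamete is
    built per chromosome with a Poisson crossover count (uniform breakpoints,
    no interference); an F2 genotype is the sum of two independent gametes.
    Phenotype follows the causal-locus genotype: homozygous-causal animals
    are high-seizing with probability ``penetrance``, everything else is
    non-seizing.

    ``loci`` restricts the genotyped loci (default: all A- and B-specific
    loci).  The causal locus must be strain-A specific.
    """
    rng = np.random.default_rng(cfg.seed + 303)
    causal = sim.causal_locus
    if cfg.plant_causal:
        if causal is None:
            raise ValueError("no causal locus planted in this simulation")
        row = sim.truth[(sim.truth["chrom"] == causal.chrom)
                        & (sim.truth["pos"] == causal.pos)]
        if row.empty or row.iloc[0]["category"] != "A":
            raise ValueError("causal locus must be a strain-A-specific variant")

    if loci is None:
        loci = sim.loci("A") + sim.loci("B")
    loci = list(loci)
    if causal is not None and causal not in loci:
        loci.append(causal)
    cat = dict(zip(
        (Locus(r.chrom, int(r.pos), r.ref, r.alt)
         for r in sim.truth.itertuples(index=False)),
        sim.truth["category"],
    ))
    by_chrom: dict[str, tuple[np.ndarray, list[Locus]]] = {}
    for chrom, _ in cfg.genome:
        members = sorted((l for l in loci if l.chrom == chrom), key=lambda l: l.pos)
        if members:
            by_chrom[chrom] = (np.array([l.pos for l in members], dtype=float), members)
    chrom_len = dict(cfg.genome)

    mean_x = cfg.cross.crossovers_per_chrom_mean
    animals = []
    for i in range(cfg.cross.n_f2):
        genotypes: dict[Locus, int] = {}
        for _gamete in range(2):
            for chrom, (positions, members) in by_chrom.items():
                n_x = rng.poisson(mean_x)
                start = int(rng.integers(2))  # 0 = strain A haplotype
                if n_x:
                    breaks = np.sort(rng.uniform(0, chrom_len[chrom], size=n_x))
                    origin = (start + np.searchsorted(breaks, positions)) % 2
                else:
                    origin = np.full(len(positions), start)
                for locus, o in zip(members, origin):
                    allele = 1 if ((o == 0) == (cat[locus] == "A")) else 0
                    genotypes[locus] = genotypes.get(locus, 0) + allele
        zyg = {
            locus: (Zygosity.HOM_ALT, Zygosity.HET, Zygosity.HOM_REF)[2 - n]
            for locus, n in genotypes.items()
        }
        phenotype = Phenotype.NON_SEIZING
        if causal is not None and zyg.get(causal) is Zygosity.HOM_ALT:
            if rng.random() < cfg.cross.penetrance:
                phenotype = Phenotype.HIGH_SEIZING
        animals.append(F2Animal(f"F2_{i:05d}", phenotype, zyg))
    return F2Cohort(animals)


def select_extremes(cohort: F2Cohort, causal: Locus,
                    n_cases: int = 2, n_controls: int = 2) -> F2Cohort:
    """Pick phenotype-extreme animals: homozygous-causal high-seizing cases
    and causal-allele-free non-seizing controls, mirroring a 2 + 2 design."""
    cases = [a for a in cohort.animals
             if a.phenotype is Phenotype.HIGH_SEIZING
             and a.genotype(causal) is Zygosity.HOM_ALT]
    controls = [a for a in cohort.animals
                if a.phenotype is Phenotype.NON_SEIZING
                and a.genotype(causal) is Zygosity.HOM_REF]
    if len(cases) < n_cases or len(controls) < n_controls:
        raise ValueError(
            f"cohort holds {len(cases)} eligible cases / {len(controls)} "
            f"eligible controls; need {n_cases} + {n_controls}")
    return F2Cohort(cases[:n_cases] + controls[:n_controls])


def simulate_cnvs(cfg: SimConfig) -> tuple[list[CnvCall], list[CnvCall], pd.DataFrame]:
    """CNV calls for both strains with planted shared/specific/unqualified truth.

    Returns (calls_a, calls_b, truth) where truth labels each planted event
    {shared, A, B, unqualified}.  When ``cfg.cnv_truth`` is supplied those
    calls are used verbatim instead of random generation.
    """
    if cfg.cnv_truth:
        calls_a = [c for c in cfg.cnv_truth if c.strain == "A"]
        calls_b = [c for c in cfg.cnv_truth if c.strain == "B"]
        truth = pd.DataFrame(
            [{"strain": c.strain, "chrom": c.chrom, "start": c.start,
              "end": c.end, "label": "supplied"} for c in cfg.cnv_truth])
        return calls_a, calls_b, truth

    rng = np.random.default_rng(cfg.seed + 404)
    c = cfg.cnv
    autosomes = [(ch, l) for ch, l in cfg.genome if ch != "X"]
    used: list[tuple[str, int, int]] = []

    def place(length: int) -> tuple[str, int, int]:
        for _ in range(1000):
            chrom, clen = autosomes[int(rng.integers(len(autosomes)))]
            if clen <= 2 * length:
                continue
            start = int(rng.integers(0, clen - length))
            end = start + length
            if all(ch != chrom or end <= s or start >= e for ch, s, e in used):
                used.append((chrom, start, end))
                return chrom, start, end
        raise ValueError("genome too small to place the requested CNVs")

    def qualified_call(strain: str) -> CnvCall:
        length = int(rng.integers(c.min_length, c.max_length))
        chrom, start, end = place(length)
        if rng.random() < 0.5:
            return CnvCall(strain, chrom, start, end, CnvKind.DEL, 0.0)
        return CnvCall(strain, chrom, start, end, CnvKind.DUP,
                       float(rng.uniform(2.0, 4.0)))

    calls_a, calls_b, rows = [], [], []
    for _ in range(c.n_shared):
        call = qualified_call("A")
        twin = CnvCall("B", call.chrom, call.start, call.end, call.kind, call.fold)
        calls_a.append(call)
        calls_b.append(twin)
        rows.append({"strain": "both", "chrom": call.chrom, "start": call.start,
                     "end": call.end, "kind": call.kind.name, "label": "shared"})
    for strain, bucket, n in (("A", calls_a, c.n_a_specific),
                              ("B", calls_b, c.n_b_specific)):
        for _ in range(n):
            call = qualified_call(strain)
            bucket.append(call)
            rows.append({"strain": strain, "chrom": call.chrom, "start": call.start,
                         "end": call.end, "kind": call.kind.name, "label": strain})
    for _ in range(c.n_unqualified):
        strain = "A" if rng.random() < 0.5 else "B"
        if rng.random() < 0.5:  # too short
            length = int(rng.integers(500, c.min_length))
            chrom, start, end = place(length)
            call = CnvCall(strain, chrom, start, end, CnvKind.DEL, 0.0)
        else:  # weak duplication
            length = int(rng.integers(c.min_length, c.max_length))
            chrom, start, end = place(length)
            call = CnvCall(strain, chrom, start, end, CnvKind.DUP,
                           float(rng.uniform(1.1, 1.9)))
        (calls_a if strain == "A" else calls_b).append(call)
        rows.append({"strain": strain, "chrom": call.chrom, "start": call.start,
                     "end": call.end, "kind": call.kind.name, "label": "unqualified"})
    return calls_a, calls_b, pd.DataFrame(rows)


def simulate_depth_tracks(cfg: SimConfig, depth_mean: Optional[float] = None,
                          gap_fraction: float = 0.02) -> list[DepthTrack]:
    """Per-base Poisson depth tracks with a random reference-gap mask."""
    rng = np.random.default_rng(cfg.seed + 505)
    mean = depth_mean if depth_mean is not None else cfg.quality.depth_mean
    tracks = []
    for chrom, length in cfg.genome:
        depths = rng.poisson(mean, size=length)
        mask = rng.random(length) < gap_fraction
        tracks.append(DepthTrack(chrom, depths, mask))
    return tracks


def write_simulation(sim: StrainSimulation, outdir) -> dict[str, Path]:
    """Write every simulated input to ``outdir`` in its standard text format."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fasta = outdir / "reference.fa"
    with open(fasta, "w") as fh:
        for chrom, seq in sim.reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    paths["reference"] = fasta

    for name, callset in (("A", sim.callset_a), ("B", sim.callset_b)):
        vcf = outdir / f"strain_{name}.vcf"
        write_strain_vcf(callset, vcf, contigs=sim.config.genome)
        paths[f"vcf_{name}"] = vcf
        cov = outdir / f"coverage_{name}.tsv"
        rows = [{"chrom": ch, "pos": pos, "depth": d, "qual": round(q, 2)}
                for (ch, pos), (d, q) in sorted(callset.coverage.items())]
        pd.DataFrame(rows, columns=["chrom", "pos", "depth", "qual"]).to_csv(
            cov, sep="\t", index=False)
        paths[f"coverage_{name}"] = cov

    truth_path = outdir / "truth.tsv"
    sim.truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path

    ann = outdir / "annotations.tsv"
    pd.DataFrame(
        [{"chrom": r.locus.chrom, "pos": r.locus.pos, "ref": r.locus.ref,
          "alt": r.locus.alt, "transcript": r.transcript,
          "consequence": r.term, "gene": r.gene} for r in sim.consequences]
    ).to_csv(ann, sep="\t", index=False)
    paths["annotations"] = ann

    panel28, panel40 = simulate_panels(sim.config, sim.truth)
    for panel in (panel28, panel40):
        p = outdir / f"{panel.name}.tsv"
        write_panel_tsv(panel, p)
        paths[panel.name] = p

    chip_records, chip_expected = simulate_chip(sim.config, sim)
    chip_path = outdir / "chip.tsv"
    write_chip_tsv(chip_records, chip_path)
    paths["chip"] = chip_path
    pd.DataFrame([chip_expected]).to_csv(outdir / "chip_expected.tsv",
                                         sep="\t", index=False)

    cohort = simulate_f2(sim.config, sim)
    write_f2_cohort(cohort, outdir / "f2_genotypes.tsv", outdir / "f2_phenotypes.tsv")
    paths["f2_genotypes"] = outdir / "f2_genotypes.tsv"
    paths["f2_phenotypes"] = outdir / "f2_phenotypes.tsv"

    calls_a, calls_b, cnv_truth = simulate_cnvs(sim.config)
    write_cnv_tsv(calls_a + calls_b, outdir / "cnvs.tsv")
    cnv_truth.to_csv(outdir / "cnv_truth.tsv", sep="\t", index=False)
    paths["cnvs"] = outdir / "cnvs.tsv"
    return paths
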