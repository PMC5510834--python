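"""Readers and writers for the standard formats the cascade touches.

VCF handling is delegated to :mod:`pysam`; everything tabular goes through
:mod:`pandas`.  All readers normalize chromosome names and loci on entry so
downstream comparisons use one locus key.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
import pysam

from .types import (
    ChipGenotype,
    CnvCall,
    CnvKind,
    ConsequenceRecord,
    DepthTrack,
    ExonModel,
    F2Animal,
    F2Cohort,
    GenomeIntervals,
    Locus,
    PanelCatalog,
    Phenotype,
    StrainCallset,
    VariantCall,
    Zygosity,
    norm_chrom,
)

PathLike = Union[str, Path]


def _zygosity_from_gt(gt: tuple, alt_index: int) -> Zygosity:
    """Map a diploid GT tuple to zygosity with respect to alt allele ``alt_index``."""
    if gt is None or any(a is None for a in gt):
        return Zygosity.MISSING
    if len(gt) != 2:
        warnings.warn(f"non-diploid genotype {gt}; treated as missing")
        return Zygosity.MISSING
    n_alt = sum(1 for a in gt if a == alt_index)
    if n_alt == 2:
        return Zygosity.HOM_ALT
    if n_alt == 1:
        return Zygosity.HET
    return Zygosity.HOM_REF


def read_strain_vcf(path: PathLike, strain: str,
                    sample: Optional[str] = None) -> StrainCallset:
    """Read per-strain variant calls from a VCF 4.x file.

    One :class:`VariantCall` is produced per biallelic record; multi-allelic
    records are split into one locus per alternate allele, with ``alt_reads``
    taken from the allele's own AD entry.  Records that cannot be parsed are
    reported as warnings, never silently dropped.

    Expected fields: FORMAT GT/DP/GQ/AD for the sample, INFO MQ and the QUAL
    column at the site level.
    """
    callset = StrainCallset(strain)
    with pysam.VariantFile(str(path)) as vcf:
        if sample is None:
            samples = list(vcf.header.samples)
            if not samples:
                raise ValueError(f"{path}: VCF has no sample columns")
            sample = samples[0]
        for rec in vcf:
            try:
                _ingest_record(callset, rec, sample)
            except Exception as exc:  # malformed record: warn, keep going
                warnings.warn(f"{path}:{rec.chrom}:{rec.pos}: skipped ({exc})")
    return callset


def _ingest_record(callset: StrainCallset, rec, sample: str) -> None:
    if rec.alts is None:
        return
    fmt = rec.samples[sample]
    missing = [f for f in ("GT", "DP") if f not in fmt or fmt.get(f) is None]
    if "DP" in missing:
        raise ValueError("missing required field DP")
    depth = int(fmt["DP"])
    gq = float(fmt.get("GQ") or 0.0)
    ad = fmt.get("AD")
    # htslib stores these as float32; round to reporting precision
    mq = round(float(rec.info.get("MQ") or 0.0), 2)
    qual = round(float(rec.qual or 0.0), 2)
    gt = fmt.get("GT")
    for i, alt in enumerate(rec.alts, start=1):
        if alt is None or set(alt.upper()) - set("ACGT"):
            warnings.warn(f"{rec.chrom}:{rec.pos}: symbolic/non-ACGT alt {alt!r} skipped")
            continue
        locus = Locus(rec.chrom, rec.pos, rec.ref, alt)
        alt_reads = 0
        if ad is not None and len(ad) > i and ad[i] is not None:
            alt_reads = int(ad[i])
        call = VariantCall(
            locus=locus,
            zygosity=_zygosity_from_gt(gt, i),
            depth=depth,
            qual=qual,
            mq=mq,
            gq=gq,
            alt_reads=min(alt_reads, depth),
        )
        callset.add(call)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
"""

_GT_STRING = {
    Zygosity.HOM_ALT: "1/1",
    Zygosity.HET: "0/1",
    Zygosity.HOM_REF: "0/0",
    Zygosity.MISSING: "./.",
}


def write_strain_vcf(callset: StrainCallset, path: PathLike,
                     contigs: Optional[Iterable[tuple[str, int]]] = None) -> None:
    """Write a callset as a plain-text single-sample VCF (used by the simulator)."""
    lines = [_VCF_HEADER]
    if contigs:
        for chrom, length in contigs:
            lines.append(f"##contig=<ID={chrom},length={length}>\n")
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{callset.strain}\n")
    for call in sorted(callset, key=lambda c: c.locus.sort_key()):
        loc = call.locus
        ref_reads = call.depth - call.alt_reads
        lines.append(
            f"{loc.chrom}\t{loc.pos}\t.\t{loc.ref}\t{loc.alt}\t{call.qual:g}\t.\t"
            f"MQ={call.mq:g}\tGT:DP:GQ:AD\t"
            f"{_GT_STRING[call.zygosity]}:{call.depth}:{int(call.gq)}:{ref_reads},{call.alt_reads}\n"
        )
    Path(path).write_text("".join(lines))


def read_bed_intervals(path: PathLike) -> GenomeIntervals:
    """Read a 3+-column BED file into a merged interval collection.

    BED is 0-based half-open; malformed records (start >= end) are rejected
    with a warning and skipped.
    """
    intervals = GenomeIntervals()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                warnings.warn(f"{path}:{lineno}: fewer than 3 BED columns, skipped")
                continue
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                warnings.warn(f"{path}:{lineno}: start >= end ({start} >= {end}), rejected")
                continue
            intervals.add(chrom, start, end)
    return intervals.merge()


def write_report(table: pd.DataFrame, path: PathLike) -> None:
    """Write a stage report as TSV with a header row and deterministic order.

    Rows are sorted by whichever of (strain, chrom, pos) columns are present.
    """
    df = table.copy()
    sort_cols = [c for c in ("chrom", "pos", "strain") if c in df.columns]
    if sort_cols:
        df = df.sort_values(sort_cols, kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_panel_tsv(path: PathLike, name: Optional[str] = None,
                   n_strains: Optional[int] = None) -> PanelCatalog:
    """Read a panel catalog TSV: chrom, pos, ref, alt, count, n_strains."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if n_strains is None:
        n_strains = int(df["n_strains"].iloc[0]) if len(df) else 1
    panel = PanelCatalog(name or Path(path).stem, n_strains)
    for row in df.itertuples(index=False):
        panel.set_count(Locus(row.chrom, row.pos, row.ref, row.alt), row.count)
    return panel


def write_panel_tsv(panel: PanelCatalog, path: PathLike) -> None:
    rows = [
        {"chrom": loc.chrom, "pos": loc.pos, "ref": loc.ref, "alt": loc.alt,
         "count": count, "n_strains": panel.n_strains}
        for loc, count in panel.presence.items()
    ]
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "count", "n_strains"])
    write_report(df, path)


def read_chip_tsv(path: PathLike) -> list[ChipGenotype]:
    """Read chip genotypes: snp_id, chrom, pos, reference_allele, array_bn_allele, polymorphic."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        ChipGenotype(
            snp_id=str(row.snp_id), chrom=row.chrom, pos=int(row.pos),
            reference_allele=row.reference_allele,
            array_bn_allele=row.array_bn_allele,
            array_call=bool(row.polymorphic),
        )
        for row in df.itertuples(index=False)
    ]


def write_chip_tsv(records: Iterable[ChipGenotype], path: PathLike) -> None:
    df = pd.DataFrame(
        [{"snp_id": r.snp_id, "chrom": r.chrom, "pos": r.pos,
          "reference_allele": r.reference_allele,
          "array_bn_allele": r.array_bn_allele,
          "polymorphic": int(r.array_call)} for r in records]
    )
    write_report(df, path)


def read_cnv_tsv(path: PathLike) -> list[CnvCall]:
    """Read CNV calls: strain, chrom, start, end, kind, fold."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        CnvCall(strain=str(row.strain), chrom=row.chrom,
                start=int(row.start), end=int(row.end),
                kind=CnvKind[str(row.kind).upper()], fold=float(row.fold))
        for row in df.itertuples(index=False)
    ]


def write_cnv_tsv(calls: Iterable[CnvCall], path: PathLike) -> None:
    df = pd.DataFrame(
        [{"strain": c.strain, "chrom": c.chrom, "start": c.start,
          "end": c.end, "kind": c.kind.name, "fold": c.fold} for c in calls]
    )
    write_report(df, path)


def read_consequence_tsv(path: PathLike) -> list[ConsequenceRecord]:
    """Read VEP-like annotations: chrom, pos, ref, alt, transcript, consequence, gene."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        ConsequenceRecord(
            locus=Locus(row.chrom, row.pos, row.ref, row.alt),
            transcript=str(row.transcript), term=str(row.consequence),
            gene=str(row.gene),
        )
        for row in df.itertuples(index=False)
    ]


def read_f2_cohort(genotypes_path: PathLike, phenotypes_path: PathLike) -> F2Cohort:
    """Read an F2 cohort from a genotype table and a phenotype table.

    Genotypes: chrom, pos, ref, alt, then one column per animal holding
    hom_alt/het/hom_ref/missing.  Phenotypes: animal_id, phenotype.
    """
    pheno = pd.read_csv(phenotypes_path, sep="\t")
    animals = {
        str(row.animal_id): F2Animal(str(row.animal_id),
                                     Phenotype(str(row.phenotype).lower()))
        for row in pheno.itertuples(index=False)
    }
    geno = pd.read_csv(genotypes_path, sep="\t", dtype={"chrom": str})
    animal_cols = [c for c in geno.columns if c not in ("chrom", "pos", "ref", "alt")]
    unknown = [c for c in animal_cols if c not in animals]
    if unknown:
        raise ValueError(f"genotype columns without phenotype entries: {unknown}")
    for row in geno.itertuples(index=False):
        locus = Locus(row.chrom, row.pos, row.ref, row.alt)
        for col in animal_cols:
            animals[col].genotypes[locus] = Zygosity(str(getattr(row, col)).lower())
    return F2Cohort(list(animals.values()))


def write_f2_cohort(cohort: F2Cohort, genotypes_path: PathLike,
                    phenotypes_path: PathLike) -> None:
    loci = sorted({loc for a in cohort.animals for loc in a.genotypes},
                  key=lambda l: l.sort_key())
    rows = []
    for loc in loci:
        row = {"chrom": loc.chrom, "pos": loc.pos, "ref": loc.ref, "alt": loc.alt}
        for animal in cohort.animals:
            row[animal.animal_id] = animal.genotype(loc).value
        rows.append(row)
    pd.DataFrame(rows).to_csv(genotypes_path, sep="\t", index=False)
    pd.DataFrame(
        [{"animal_id": a.animal_id, "phenotype": a.phenotype.value}
         for a in cohort.animals]
    ).to_csv(phenotypes_path, sep="\t", index=False)


def read_depth_track(path: PathLike, chrom_length: Optional[dict[str, int]] = None,
                     gap_intervals: Optional[GenomeIntervals] = None) -> list[DepthTrack]:
    """Read per-base depths (chrom, pos, depth; 1-based) into DepthTracks.

    Positions absent from the file have depth 0.  ``gap_intervals`` marks
    reference-gap positions to exclude from denominators.
    """
    import numpy as np

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    tracks = []
    for chrom, grp in df.groupby("chrom", sort=True):
        chrom = norm_chrom(chrom)
        length = (chrom_length or {}).get(chrom, int(grp["pos"].max()))
        depths = np.zeros(length, dtype=np.int64)
        pos = grp["pos"].to_numpy(dtype=np.int64)
        depths[pos - 1] = grp["depth"].to_numpy(dtype=np.int64)
        mask = np.zeros(length, dtype=bool)
        if gap_intervals is not None:
            for start, end in gap_intervals.intervals(chrom):
                mask[start:min(end, length)] = True
        tracks.append(DepthTrack(chrom, depths, mask))
    return tracks


def read_exon_bed(path: PathLike) -> ExonModel:
    """Read exon intervals with gene names from a 4+-column BED (name = gene)."""
    model = ExonModel()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                warnings.warn(f"{path}:{lineno}: exon BED needs 4 columns, skipped")
                continue
            model.add_exon(parts[0], int(parts[1]), int(parts[2]), parts[3])
    return model
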