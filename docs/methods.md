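# Methods

## The study design being modeled

Two inbred strains are derived from one founder colony by selective breeding
for the presence versus absence of a phenotype, and both are whole-genome
sequenced against a common reference assembly. Because the strains are
inbred, true variants are homozygous; the genetic difference between the
lines is a set of strain-specific homozygous variants. Candidates for the
phenotype are narrowed in a cascade — evidence filtering, consequence
classification, external-panel screens — and finally tested for
co-segregation with phenotype in F2 intercross progeny sequenced at the
phenotype extremes. This package implements each stage as a pure function
over explicit domain types, so stages can be run, tested and recombined
independently.

## Stage definitions and conventions

**Coordinates and identity.** All variant-facing APIs are 1-based; BED
inputs (0-based, half-open) are converted on read. A locus is identified by
(chromosome, position, ref, alt) after normalization: a leading `chr` is
stripped from chromosome names, and indel alleles are trimmed of shared
trailing then leading bases (left alignment), bumping the position per
leading base removed. Without this normalization, the same indel read from
different sources (strain VCFs, panel catalogs, candidate tables) would
fragment into distinct keys. All comparisons are reference-strand; no
complementation anywhere.

**Strain-specific comparison.** A variant in strain A qualifies when (i) it
is homozygous-alternate with depth ≥ 3 and QUAL ≥ 30 (inclusive, as for all
thresholds here); (ii) strain B has no matching call — by default matching
requires the same alternate allele (`MatchKey.POSITION_ALLELE`); a
position-only key is available since either reading is defensible; a HET
call in B counts as presence (the conservative reading); an explicit
HOM_REF call does not; and (iii) strain B's evidence at the site itself
meets depth ≥ 3 and QUAL ≥ 30, taken from B's call at the position if any,
else from its coverage track. Candidates failing (iii) are tallied as
*omitted for low evidence* rather than counted as specific. Indels whose
reference span overlaps a reference-gap interval are excluded outright.

**Consequence collapse.** The vocabulary is closed (15 SNV terms, 13 indel
terms) with a fixed severity order; one term per variant is chosen by
precedence, and a synonym table maps Ensembl-VEP consequence strings onto
the vocabulary so real annotation output can be consumed. Note one
deliberate quirk preserved from the vocabulary's severity order: for SNVs,
*synonymous* precedes *splice region variant*, so a variant annotated with
both collapses to synonymous. When transcripts tie at the same precedence,
the gene of the first transcript in sorted order is attributed — an
arbitrary but deterministic rule. Loci with no annotation collapse to
intergenic.

**High-confidence filter.** The five criteria (depth ≥ 10, QUAL ≥ 30,
MQ ≥ 40, GQ ≥ 20, alt-fraction ≥ 0.80) are evaluated per call with
inclusive boundaries; the alt fraction uses total reads at the site as
denominator. A record claiming alt reads at zero depth is malformed and
rejected with a warning.

**Panel screens.** Privacy requires presence count 0 in every panel;
loci absent from a catalog have implicit count 0. The frequency screen
keeps variants strictly below a per-panel exclusive threshold in *every*
panel (conjunction); the default pair is <4 of 28 and <5 of 40.

**F2 screens.** STRICT requires HOM_ALT in every case animal; PERMISSIVE
requires at least one alternate allele in every case animal; both require
zero alternate alleles in every control. "Absent among controls" means no
alt allele, not merely non-homozygous. A MISSING genotype in a case fails
the candidate (presence unproven); MISSING in a control fails by default
(absence unproven) and can be relaxed (`missing_control_fails=False`).
STRICT survivors are a subset of PERMISSIVE survivors by construction, and
the property is tested on random cohorts. Block reports give, per
chromosome, the minimal interval covering the survivors; the span is
end − start on 1-based inclusive coordinates (the distance between the
outermost members), which is the convention that reproduces published
block spans from their printed endpoints.

**CNV rules.** Deletions must be complete losses (fold = 0; a configurable
tolerance `del_max_fold` accommodates noisy fold estimates) and
duplications ≥ 2-fold, both ≥ 5 kb. "2-fold" is read as copy-ratio ≥ 2
rather than "copy number ≥ 4"; the threshold is a parameter. Cross-strain
matching uses ≥ 50% reciprocal overlap of same-kind events (configurable)
because read-depth breakpoints are imprecise and exact interval equality
would call nearly everything specific.

**Concordance.** Detection is site-level: a chip-polymorphic SNP counts as
detected when the callset holds any non-reference call at the position with
depth ≥ 3 and QUAL ≥ 30, matching how array polymorphic/non-polymorphic
assignments are defined. Sensitivity and specificity are percentages of the
chip-assigned polymorphic and non-polymorphic sets, with no coverage-based
exclusions by default. Discordances where the array's own reference-strain
allele disagrees with the assembly base are attributed to suspect reference
positions. Percentages are rounded to two decimals; one published
specificity figure (98.29% for the control strain) is not reproducible from
its own published counts (8,440/8,624 = 97.87%), so the implementation
reports the recomputed value and makes no attempt to reconcile the printed
one.

**Coverage.** Average depth and per-threshold fractions (≥1, 3, 5, 10, 15,
20 reads, inclusive) are computed over non-gap bases only, separately for
autosomes and X. The inclusive reading is used where a source table header
ambiguously says ">t reads" but its text says "at least t".

## The synthetic-data generator

The generator emulates the *structure* of the study — not its scale. Default
conditions, chosen once: a 2 Mb genome (four autosomes + X, 400 kb each);
1,500 shared plus 1,000 + 1,000 strain-specific variants, 20% indels;
30% of specific variants private to their strain; 2% non-synonymous; 5% of
other-strain sites under-covered (depth < 3) to exercise the omission rule.
Evidence fields for true calls are anchored on a short-read profile of
~15× mean depth and consensus quality ~58; 35% of true calls are drawn to
fail exactly one of the five high-confidence criteria, approximating the
~64% pass rate such data show at those thresholds. External panels have 28
and 40 strains; panel-seen loci draw counts as 1 + Binomial(n−1, 0.08).
The chip assays 2,000 SNPs, half at carried variant sites, with
configurable polymorphic-flag error and reference-allele error rates, and
emits an analytically derived expected confusion table. Every stream of
randomness derives from one seed; identical configs produce byte-identical
outputs.

**The cross.** Both F1 parents are obligate heterozygotes carrying one
haplotype from each strain. Gametes are formed per chromosome with a
Poisson crossover count (default mean 1), uniform breakpoint positions and
no interference — the simplest model consistent with a double-cross design.
Phenotype is deterministic by default (homozygous causal → high-seizing,
otherwise non-seizing; a penetrance parameter adds noise if wanted), which
reproduces the extreme-phenotype selection the design relies on. Simulated
animals are treated as female, so X segregates like an autosome. The
planted causal variant must be specific to the case strain, mirrored by a
hard error otherwise.

**What the generator does not model** — and hence what passing tests do not
show about real data: read-level errors and mapping artifacts (evidence
fields are drawn from distributions, not pileups), linkage-map structure of
a real genome (uniform recombination, no hotspots or interference),
population structure within panels (independent carriage draws), shared
variants appearing in panels, and polygenic phenotype contributions
(single planted causal locus). Genome-scale counts from real studies
(millions of variants) are therefore out of reach at desk scale by design;
correctness is instead established by exact recovery of planted truth and
by closed-form statistical checks (Mendelian 1:2:1 segregation, allele
frequency ½, recombination fractions under the uniform-breakpoint model,
chance co-segregation probability (1/4)⁴ for a 2+2 cohort).

## Numerical choices

Percentages are rounded with Python's `round` to two decimals (one decimal
for coverage tables and Mbp spans), which matches all published figures
checked in the tests. QUAL/MQ values read through htslib are float32 and
are rounded to two decimals on ingest so write→read round trips are exact.
Cascade tiers must be nested; a non-nested tier is a wiring bug and raises.
Zero denominators report 0.0 (empty-tally percentage, empty discordant set)
or `None`/not-applicable (FP profile of an empty set) rather than NaN.

## Problem sizes

The bundled test-suite and acceptance runs use the desk-scale defaults
above (thousands of variants, F2 cohorts of 200–10,000); the full suite
runs in well under a minute and the acceptance script in seconds. All sizes
are configuration, not code: a larger genome or cohort is a `SimConfig`
change.

## Known limitations

Only biallelic, diploid genotypes are supported (other ploidies parse as
missing with a warning). Liftover to another assembly is consumed as an
externally supplied per-variant flag; no chain mapping is performed. The
annotation stage collapses supplied consequence records; it does not predict
consequences from gene models. CNV calling itself is upstream; only the
qualification and screening rules are implemented here.
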