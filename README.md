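# strainscreen

Variant prioritization for two-inbred-strain study designs: one strain
carrying a spontaneously arisen phenotype (e.g. absence epilepsy in a rat
line), one related control strain bred from the same founder colony, both
whole-genome sequenced against a common reference assembly, plus
second-generation (F2) intercross progeny sequenced at the phenotype
extremes.

The package turns raw per-strain variant calls into a short, ranked
candidate list by composing the screens such a study needs:

- **Strain-specific variants** — homozygous calls with ≥3-fold coverage and
  QUAL ≥ 30 in one strain, absent from the other strain *where the other
  strain's own data are adequate*; under-covered sites are omitted, not
  counted (absence of evidence ≠ evidence of absence).
- **Consequence collapse** — a variant overlapping several transcripts gets
  one term by fixed severity precedence (stop gain ≻ stop loss ≻ essential
  splice ≻ missense ≻ … ≻ intergenic); non-synonymous variants
  (missense, nonsense, essential splice, frameshift, in-frame codon indels)
  feed the cascade.
- **High-confidence filter** — the five evidence criteria
  depth ≥ 10, QUAL ≥ 30, MQ ≥ 40, GQ ≥ 20 and alt-supporting read fraction
  ≥ 0.80 (all boundaries inclusive), plus repeat-mask exclusion for indels.
- **Panel screens** — *privacy* (absent from every external strain panel)
  and *frequency* (present in fewer than k carriers in every panel, default
  <4 of 28 and <5 of 40).
- **F2 co-segregation** — strict (homozygous in every case animal, no alt
  allele in any control) and permissive ("irrespective of zygosity")
  screens across extreme-phenotype F2 animals, with per-chromosome block
  reports of the survivors.
- **CNV qualification** — ≥5 kb, complete-loss deletions or ≥2-fold
  duplications, cross-strain reciprocal-overlap matching, exon overlap and
  phenotype-gene-list intersection.
- **QC** — chip-versus-sequencing concordance (sensitivity/specificity at
  depth ≥ 3, QUAL ≥ 30, FP/FN decomposition, attribution of discordances to
  suspect reference bases) and depth-threshold coverage summaries excluding
  reference gaps.

A full synthetic-data generator (`strainscreen.simulate`) produces every
input the cascade consumes — two inbred strains, external panels, a
genotyping chip, an F1×F1 cross with Poisson recombination and a planted
causal variant, CNVs, depth tracks — with a ground-truth table, so the whole
pipeline runs and is testable without any external data.

## Worked example

```python
from strainscreen import strain_specific_variants, tally_table
from strainscreen.simulate import SimConfig, simulate_strains

sim = simulate_strains(SimConfig(seed=42))
set_a, set_b = strain_specific_variants(sim.callset_a, sim.callset_b)
print(tally_table(set_a, set_b).to_string(index=False))
```

prints

```
strain variant_type  variants  homozygous  strain_specific  strain_specific_pct
     A          SNV      1815        1815              682                37.58
     A        INDEL       495         495              194                39.19
     B          SNV      1863        1863              721                38.70
     B        INDEL       459         459              172                37.47
```

Each row tallies one strain and variant class: calls meeting the evidence
thresholds, the homozygous subset, and how many of those are specific to
that strain (with the percentage of homozygous calls). Because the
simulated strains are fully inbred, every call is homozygous. Continuing
through the cascade and the F2 screen (`examples/03_f2_cosegregation.py`):

```
candidates entering the F2 screen: 274 private strain-A variants (causal variant planted at 1:356T>A)
F2 cohort: 300 animals; selected extremes: ['F2_00005', 'F2_00016', 'F2_00000', 'F2_00002']
strict survivors: 1 (causal retained: True)
permissive survivors: 3 (strict is always a subset)
```

Of 274 private strain-A candidates only the planted causal variant is
homozygous in both high-seizing animals and absent from both non-seizing
animals; the permissive screen admits two additional chance/linked
co-segregants.

The `examples/` directory holds one short script per capability
(simulation + comparison, candidate cascade, F2 screen, concordance QC,
CNV + coverage). A thin CLI mirrors the same stages:
`strainscreen strain-compare|annotate-summary|filter|f2-screen|cnv-screen|concordance|coverage|simulate`.

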