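"""F2 co-segregation screens, cross simulation genetics and block analysis."""

import numpy as np
import pytest

from strainscreen import (
    F2Animal,
    F2Cohort,
    Locus,
    PanelCatalog,
    Phenotype,
    ScreenMode,
    Zygosity,
    block_scan,
    combined_screen,
    segregation_screen,
)
from strainscreen.simulate import (
    CrossConfig,
    QualityModel,
    SimConfig,
    select_extremes,
    simulate_f2,
    simulate_strains,
)

HIGH, NON = Phenotype.HIGH_SEIZING, Phenotype.NON_SEIZING
HOM, HET, REF, MISS = (Zygosity.HOM_ALT, Zygosity.HET, Zygosity.HOM_REF,
                       Zygosity.MISSING)


def _cohort(locus, case_gts, control_gts):
    animals = [F2Animal(f"case{i}", HIGH, {locus: g})
               for i, g in enumerate(case_gts)]
    animals += [F2Animal(f"ctrl{i}", NON, {locus: g})
                for i, g in enumerate(control_gts)]
    return F2Cohort(animals)


class TestSegregationScreen:
    LOC = Locus("10", 14629759, "C", "G")

    def test_homozygous_cases_absent_controls_survive_strict(self):
        cohort = _cohort(self.LOC, [HOM, HOM], [REF, REF])
        assert segregation_screen([self.LOC], cohort, HIGH) == {self.LOC}

    def test_het_case_fails_strict_but_survives_permissive(self):
        cohort = _cohort(self.LOC, [HET, HOM], [REF, REF])
        strict = segregation_screen([self.LOC], cohort, HIGH, ScreenMode.STRICT)
        permissive = segregation_screen([self.LOC], cohort, HIGH,
                                        ScreenMode.PERMISSIVE)
        assert strict == set() and permissive == {self.LOC}

    def test_any_carrier_control_fails_both_modes(self):
        for bad in (HET, HOM):
            cohort = _cohort(self.LOC, [HOM, HOM], [REF, bad])
            for mode in ScreenMode:
                assert segregation_screen([self.LOC], cohort, HIGH, mode) == set()

    def test_missing_genotypes_are_conservative(self):
        in_case = _cohort(self.LOC, [HOM, MISS], [REF, REF])
        in_ctrl = _cohort(self.LOC, [HOM, HOM], [REF, MISS])
        assert segregation_screen([self.LOC], in_case, HIGH) == set()
        assert segregation_screen([self.LOC], in_ctrl, HIGH) == set()
        relaxed = segregation_screen([self.LOC], in_ctrl, HIGH,
                                     missing_control_fails=False)
        assert relaxed == {self.LOC}

    def test_cohort_without_both_phenotypes_is_fatal(self):
        cohort = F2Cohort([F2Animal("a", HIGH, {self.LOC: HOM})])
        with pytest.raises(ValueError):
            segregation_screen([self.LOC], cohort, HIGH)

    def test_case_control_swap_mirrors_the_screen(self):
        loc_b = Locus("7", 100, "A", "G")
        animals = [
            F2Animal("h1", HIGH, {self.LOC: HOM, loc_b: REF}),
            F2Animal("h2", HIGH, {self.LOC: HOM, loc_b: REF}),
            F2Animal("n1", NON, {self.LOC: REF, loc_b: HOM}),
            F2Animal("n2", NON, {self.LOC: REF, loc_b: HOM}),
        ]
        cohort = F2Cohort(animals)
        assert segregation_screen([self.LOC, loc_b], cohort, HIGH) == {self.LOC}
        assert segregation_screen([self.LOC, loc_b], cohort, NON) == {loc_b}

    @pytest.mark.parametrize("seed", range(20))
    def test_strict_is_subset_of_permissive_on_random_cohorts(self, seed):
        rng = np.random.default_rng(seed)
        loci = [Locus("1", 10 + 10 * i, "A", "G") for i in range(30)]
        zygs = [HOM, HET, REF, MISS]
        animals = [
            F2Animal(f"a{i}", HIGH if i < 2 else NON,
                     {l: zygs[rng.integers(4)] for l in loci})
            for i in range(4)
        ]
        cohort = F2Cohort(animals)
        strict = segregation_screen(loci, cohort, HIGH, ScreenMode.STRICT)
        permissive = segregation_screen(loci, cohort, HIGH, ScreenMode.PERMISSIVE)
        assert strict <= permissive


class TestCombinedScreen:
    def test_frequency_component_drops_common_survivors(self):
        loc_rare = Locus("1", 10, "A", "G")
        loc_common = Locus("1", 20, "C", "T")
        cohort = _cohort(loc_rare, [HOM, HOM], [REF, REF])
        for a in cohort.animals:
            a.genotypes[loc_common] = a.genotypes[loc_rare]
        p28 = PanelCatalog("panel28", 28, {loc_common: 4})
        p40 = PanelCatalog("panel40", 40, {loc_rare: 4})
        report = combined_screen(
            [loc_rare, loc_common], cohort, HIGH, [p28, p40],
            {"panel28": 4, "panel40": 5}, gene_map={loc_rare: "Cacna1h"},
            strain="A")
        assert list(report["variant"]) == ["1:10A>G"]
        assert list(report["gene"]) == ["Cacna1h"]
        assert list(report["panel40_count"]) == [4]

    def test_empty_candidates_give_empty_report(self):
        cohort = _cohort(Locus("1", 10, "A", "G"), [HOM], [REF])
        report = combined_screen([], cohort, HIGH, [], {})
        assert len(report) == 0


class TestBlockScan:
    def test_single_survivor_has_zero_span(self):
        [block] = block_scan([Locus("7", 1000, "A", "G")])
        assert block.span_bp == 0 and block.n_inside == 1

    def test_two_chromosomes_give_two_blocks(self):
        loci = [Locus("7", 100, "A", "G"), Locus("7", 900, "C", "T"),
                Locus("1", 400, "G", "A")]
        blocks = {b.chrom: b for b in block_scan(loci)}
        assert set(blocks) == {"1", "7"}
        assert blocks["7"].span_bp == 800
        assert blocks["7"].n_inside == 2 and blocks["7"].n_total == 3
        assert blocks["1"].span_bp == 0

    def test_span_matches_brute_force_min_max(self):
        rng = np.random.default_rng(0)
        loci = [Locus(str(rng.integers(1, 4)), int(rng.integers(1, 10**8)),
                      "A", "G") for _ in range(200)]
        for block in block_scan(loci):
            positions = [l.pos for l in loci if l.chrom == block.chrom]
            assert block.start_pos == min(positions)
            assert block.end_pos == max(positions)
            assert block.span_bp == max(positions) - min(positions)

    def test_no_survivors_is_an_error(self):
        with pytest.raises(ValueError):
            block_scan([])


@pytest.fixture(scope="module")
def cross_sim():
    cfg = SimConfig(
        seed=23,
        genome=(("1", 500_000), ("2", 500_000)),
        n_shared=0, n_a_specific=20, n_b_specific=20,
        low_coverage_fraction=0.0,
        quality=QualityModel(hc_fail_fraction=0.0),
        cross=CrossConfig(n_f2=2000),
    )
    sim = simulate_strains(cfg)
    return sim, simulate_f2(cfg, sim)


class TestCrossGenetics:
    def test_parental_strains_carry_no_het_calls(self, cross_sim):
        sim, _ = cross_sim
        for callset in (sim.callset_a, sim.callset_b):
            assert all(c.zygosity is Zygosity.HOM_ALT for c in callset)

    def test_unlinked_locus_segregates_1_2_1(self, cross_sim):
        sim, cohort = cross_sim
        causal = sim.causal_locus
        locus = next(l for l in sim.loci("A") if l.chrom != causal.chrom)
        n = len(cohort)
        counts = {z: 0 for z in (HOM, HET, REF)}
        for a in cohort.animals:
            counts[a.genotype(locus)] += 1
        # 3 binomial SDs around 25 / 50 / 25 %
        sd25 = (0.25 * 0.75 / n) ** 0.5
        sd50 = (0.5 * 0.5 / n) ** 0.5
        assert abs(counts[HOM] / n - 0.25) < 3 * sd25
        assert abs(counts[HET] / n - 0.50) < 3 * sd50
        assert abs(counts[REF] / n - 0.25) < 3 * sd25

    def test_allele_frequency_is_half(self, cross_sim):
        sim, cohort = cross_sim
        for locus in sim.loci("A")[:5]:
            alleles = sum({HOM: 2, HET: 1, REF: 0}[a.genotype(locus)]
                          for a in cohort.animals)
            freq = alleles / (2 * len(cohort))
            assert abs(freq - 0.5) < 3 * (0.25 / (2 * len(cohort))) ** 0.5

    def test_phenotype_follows_causal_genotype(self, cross_sim):
        sim, cohort = cross_sim
        causal = sim.causal_locus
        for a in cohort.animals:
            expected = HIGH if a.genotype(causal) is HOM else NON
            assert a.phenotype is expected

    def test_zero_crossovers_give_intact_parental_haplotypes(self):
        cfg = SimConfig(
            seed=9, genome=(("1", 500_000),), n_shared=0,
            n_a_specific=15, n_b_specific=0, low_coverage_fraction=0.0,
            quality=QualityModel(hc_fail_fraction=0.0),
            cross=CrossConfig(n_f2=50, crossovers_per_chrom_mean=0.0),
        )
        sim = simulate_strains(cfg)
        cohort = simulate_f2(cfg, sim, loci=sim.loci("A"))
        for a in cohort.animals:
            gts = {a.genotype(l) for l in sim.loci("A")}
            assert len(gts) == 1  # whole chromosome inherited en bloc

    def test_recombination_fraction_matches_uniform_breakpoint_model(self):
        """Joint genotypes at two linked loci follow the closed-form gamete
        distribution under Poisson crossovers with uniform breakpoints."""
        chrom_len = 10_000_000
        cfg = SimConfig(
            seed=31, genome=(("1", chrom_len),), n_shared=0,
            n_a_specific=2, n_b_specific=0, low_coverage_fraction=0.0,
            quality=QualityModel(hc_fail_fraction=0.0), plant_causal=False,
            cross=CrossConfig(n_f2=8000, crossovers_per_chrom_mean=1.0),
        )
        sim = simulate_strains(cfg)
        l1, l2 = sorted(sim.loci("A"), key=lambda l: l.pos)
        d = l2.pos - l1.pos
        # P(odd number of crossovers between the loci)
        lam = d / chrom_len * 1.0
        p_rec = (1 - np.exp(-2 * lam)) / 2
        cohort = simulate_f2(cfg, sim, loci=[l1, l2])
        # gamete haplotype probabilities: (alt,alt) (ref,ref) parental,
        # (alt,ref) (ref,alt) recombinant
        hap = {(1, 1): (1 - p_rec) / 2, (0, 0): (1 - p_rec) / 2,
               (1, 0): p_rec / 2, (0, 1): p_rec / 2}
        expected = {}
        for (a1, a2), p in hap.items():
            for (b1, b2), q in hap.items():
                key = (a1 + b1, a2 + b2)
                expected[key] = expected.get(key, 0.0) + p * q
        counts = {}
        code = {HOM: 2, HET: 1, REF: 0}
        for animal in cohort.animals:
            key = (code[animal.genotype(l1)], code[animal.genotype(l2)])
            counts[key] = counts.get(key, 0) + 1
        n = len(cohort)
        for key, p in expected.items():
            if p < 1e-5:
                continue
            sd = (p * (1 - p) / n) ** 0.5
            assert abs(counts.get(key, 0) / n - p) < 4 * sd + 1e-9, key

    def test_extreme_selection_returns_informative_animals(self, cross_sim):
        sim, cohort = cross_sim
        causal = sim.causal_locus
        extremes = select_extremes(cohort, causal)
        assert len(extremes) == 4
        for a in extremes.with_phenotype(HIGH):
            assert a.genotype(causal) is HOM
        for a in extremes.with_phenotype(NON):
            assert a.genotype(causal) is REF

    def test_planted_causal_variant_survives_strict_screen(self, cross_sim):
        sim, cohort = cross_sim
        extremes = select_extremes(cohort, sim.causal_locus)
        candidates = sim.loci("A")
        survivors = segregation_screen(candidates, extremes, HIGH,
                                       ScreenMode.STRICT)
        assert sim.causal_locus in survivors

    def test_chance_survival_rate_matches_closed_form(self):
        """For unlinked candidates screened on a 2+2 cohort the strict
        survival probability is (1/4)^2 x (1/4)^2 per locus."""
        cfg = SimConfig(
            seed=77,
            genome=tuple((str(i), 300_000) for i in range(1, 9)),
            n_shared=0, n_a_specific=40, n_b_specific=0,
            low_coverage_fraction=0.0,
            quality=QualityModel(hc_fail_fraction=0.0), plant_causal=False,
            cross=CrossConfig(n_f2=4),
        )
        from dataclasses import replace

        rng = np.random.default_rng(123)
        sim = simulate_strains(cfg)  # strains fixed; cohorts re-drawn per trial
        # one locus per chromosome so every screened locus is unlinked
        loci = []
        seen_chroms = set()
        for locus in sim.loci("A"):
            if locus.chrom not in seen_chroms:
                loci.append(locus)
                seen_chroms.add(locus.chrom)
        n_trials = 500
        total = 0
        for trial in range(n_trials):
            cfg_t = replace(cfg, seed=int(rng.integers(2**30)))
            cohort = simulate_f2(cfg_t, sim, loci=loci)
            # label 2 animals as cases and 2 as controls arbitrarily
            for i, a in enumerate(cohort.animals):
                a.phenotype = HIGH if i < 2 else NON
            total += len(segregation_screen(loci, cohort, HIGH, ScreenMode.STRICT))
        n_tests = n_trials * len(loci)
        p = (1 / 4) ** 2 * (1 / 4) ** 2  # hom-hom cases x ref-ref controls
        sd = (p * (1 - p) * n_tests) ** 0.5
        assert abs(total - p * n_tests) < 4 * sd + 1
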