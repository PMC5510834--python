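"""Strain-specific variant identification: omission rules, oracle equivalence."""

import numpy as np
import pytest

from strainscreen import (
    GenomeIntervals,
    Locus,
    MatchKey,
    StrainCallset,
    StrainCompareParams,
    VariantCall,
    Zygosity,
    strain_specific_variants,
    tally_table,
)
from strainscreen.compare import specific_percentage


def _call(chrom, pos, ref, alt, zyg=Zygosity.HOM_ALT, depth=13, qual=58.0,
          **kw):
    return VariantCall(Locus(chrom, pos, ref, alt), zyg, depth=depth,
                       qual=qual, mq=50.0, gq=60.0,
                       alt_reads=kw.pop("alt_reads", depth), **kw)


class TestRules:
    def test_specific_when_other_strain_well_covered(self):
        a = StrainCallset("A", [_call("1", 100, "A", "G")])
        b = StrainCallset("B")
        b.set_coverage("1", 100, 20, 60.0)
        sa, sb = strain_specific_variants(a, b)
        assert [c.locus for c in sa.variants] == [Locus("1", 100, "A", "G")]
        assert sa.omitted_low_evidence == 0 and not sb.variants

    def test_omitted_when_other_strain_under_covered(self):
        a = StrainCallset("A", [_call("1", 100, "A", "G")])
        b = StrainCallset("B")
        b.set_coverage("1", 100, 2, 60.0)  # < 3-fold
        sa, _ = strain_specific_variants(a, b)
        assert not sa.variants and sa.omitted_low_evidence == 1

    def test_omitted_when_other_strain_has_no_data(self):
        a = StrainCallset("A", [_call("1", 100, "A", "G")])
        sa, _ = strain_specific_variants(a, StrainCallset("B"))
        assert not sa.variants and sa.omitted_low_evidence == 1

    def test_het_call_in_other_strain_counts_as_present(self):
        a = StrainCallset("A", [_call("1", 100, "A", "G")])
        b = StrainCallset("B", [_call("1", 100, "A", "G", zyg=Zygosity.HET)])
        sa, _ = strain_specific_variants(a, b)
        assert not sa.variants and sa.omitted_low_evidence == 0

    def test_hom_ref_call_in_other_strain_is_absence_with_evidence(self):
        a = StrainCallset("A", [_call("1", 100, "A", "G")])
        b = StrainCallset("B", [_call("1", 100, "A", "G", zyg=Zygosity.HOM_REF,
                                      alt_reads=0)])
        sa, _ = strain_specific_variants(a, b)
        assert len(sa.variants) == 1

    def test_match_key_allele_vs_position(self):
        a = StrainCallset("A", [_call("1", 100, "A", "G")])
        b = StrainCallset("B", [_call("1", 100, "A", "T")])  # different alt
        allele = StrainCompareParams(match_key=MatchKey.POSITION_ALLELE)
        position = StrainCompareParams(match_key=MatchKey.POSITION_ONLY)
        sa_allele, _ = strain_specific_variants(a, b, allele)
        sa_position, _ = strain_specific_variants(a, b, position)
        assert len(sa_allele.variants) == 1  # other alt, site well covered by b's call
        assert len(sa_position.variants) == 0

    def test_het_and_low_evidence_calls_never_qualify(self):
        a = StrainCallset("A", [
            _call("1", 100, "A", "G", zyg=Zygosity.HET),
            _call("1", 200, "C", "T", depth=2),       # under-covered
            _call("1", 300, "G", "A", qual=29.0),     # below QUAL cutoff
        ])
        b = StrainCallset("B")
        for pos in (100, 200, 300):
            b.set_coverage("1", pos, 20, 60.0)
        sa, _ = strain_specific_variants(a, b)
        assert not sa.variants

    def test_indel_overlapping_reference_gap_excluded(self):
        gaps = GenomeIntervals()
        gaps.add("1", 95, 105)
        a = StrainCallset("A", [
            _call("1", 100, "ATTT", "A"),   # deletion spanning the gap
            _call("1", 500, "C", "CTT"),    # insertion far away
        ])
        b = StrainCallset("B")
        b.set_coverage("1", 100, 20, 60.0)
        b.set_coverage("1", 500, 20, 60.0)
        sa, _ = strain_specific_variants(
            a, b, StrainCompareParams(gap_intervals=gaps))
        assert [c.locus.pos for c in sa.variants] == [500]
        assert sa.gap_excluded_indels == 1


class TestTruthRecovery:
    def test_exact_recovery_on_clean_simulation(self, clean_sim):
        sa, sb = strain_specific_variants(clean_sim.callset_a, clean_sim.callset_b)
        truth = clean_sim.truth
        assert {c.locus for c in sa.variants} == set(clean_sim.loci("A"))
        assert {c.locus for c in sb.variants} == set(clean_sim.loci("B"))
        assert sa.omitted_low_evidence == 0 == sb.omitted_low_evidence
        assert len(sa.variants) == (truth["category"] == "A").sum()

    def test_under_covered_fraction_is_omitted(self, default_sim):
        """Sites where the other strain lacks >=3-fold coverage must be
        omitted, not counted as specific; the truth table is the oracle."""
        sa, sb = strain_specific_variants(default_sim.callset_a,
                                          default_sim.callset_b)
        truth = default_sim.truth
        own = {"A": default_sim.callset_a, "B": default_sim.callset_b}
        for sset, category in ((sa, "A"), (sb, "B")):
            rows = truth[truth["category"] == category]
            low = rows[rows["other_low_coverage"]]
            # candidates only reach the omission check when their own call
            # meets the contributing thresholds
            expected_omitted = 0
            got = {c.locus for c in sset.variants}
            for r in low.itertuples(index=False):
                locus = Locus(r.chrom, int(r.pos), r.ref, r.alt)
                call = own[category].get(locus)
                if call.depth >= 3 and call.qual >= 30.0:
                    expected_omitted += 1
                assert locus not in got
            assert sset.omitted_low_evidence == expected_omitted


class TestProperties:
    def _random_callsets(self, seed, n=300):
        rng = np.random.default_rng(seed)
        calls_a, calls_b = [], []
        cov_a, cov_b = {}, {}
        for i in range(n):
            pos = 10 + i * 10
            zyg = rng.choice(list(Zygosity))
            depth = int(rng.integers(0, 30))
            qual = float(rng.integers(0, 80))
            where = rng.random()
            call = VariantCall(Locus("1", pos, "A", "G"), zyg, depth=depth,
                               qual=qual, alt_reads=depth)
            if where < 0.4:
                calls_a.append(call)
                cov_b[("1", pos)] = (int(rng.integers(0, 30)), float(rng.integers(0, 80)))
            elif where < 0.8:
                calls_b.append(call)
                cov_a[("1", pos)] = (int(rng.integers(0, 30)), float(rng.integers(0, 80)))
            else:
                calls_a.append(call)
                calls_b.append(VariantCall(
                    Locus("1", pos, "A", "G"), rng.choice(list(Zygosity)),
                    depth=int(rng.integers(0, 30)), qual=float(rng.integers(0, 80))))
        return (StrainCallset("A", calls_a, cov_a),
                StrainCallset("B", calls_b, cov_b))

    def _brute_force(self, own, other, params):
        out = []
        for call in own.calls.values():
            if call.zygosity is not Zygosity.HOM_ALT:
                continue
            if call.depth < params.min_depth or call.qual < params.min_qual:
                continue
            other_call = other.calls.get(call.locus)
            if other_call is not None and other_call.zygosity in (
                    Zygosity.HET, Zygosity.HOM_ALT):
                continue
            ev = other.evidence_at(call.locus.chrom, call.locus.pos)
            if ev is None or ev[0] < params.min_depth or ev[1] < params.min_qual:
                continue
            out.append(call.locus)
        return set(out)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_nested_loop_oracle(self, seed):
        a, b = self._random_callsets(seed)
        params = StrainCompareParams()
        sa, sb = strain_specific_variants(a, b, params)
        assert {c.locus for c in sa.variants} == self._brute_force(a, b, params)
        assert {c.locus for c in sb.variants} == self._brute_force(b, a, params)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_specific_sets_are_disjoint(self, seed):
        a, b = self._random_callsets(seed)
        for key in MatchKey:
            sa, sb = strain_specific_variants(
                a, b, StrainCompareParams(match_key=key))
            assert not ({c.locus for c in sa.variants}
                        & {c.locus for c in sb.variants})

    def test_raising_thresholds_never_adds_specific_variants(self):
        a, b = self._random_callsets(7)
        base = strain_specific_variants(a, b, StrainCompareParams())[0]
        for params in (StrainCompareParams(min_depth=5),
                       StrainCompareParams(min_qual=50.0),
                       StrainCompareParams(min_depth=10, min_qual=60.0)):
            stricter = strain_specific_variants(a, b, params)[0]
            assert len(stricter.variants) <= len(base.variants)


class TestTally:
    def test_percentage_arithmetic(self):
        assert specific_percentage(1_119_180, 3_713_694) == 30.14
        assert specific_percentage(296_455, 954_008) == 31.07
        assert specific_percentage(0, 1000) == 0.0
        assert specific_percentage(0, 0) == 0.0

    def test_table_layout_and_consistency(self, clean_sim):
        sa, sb = strain_specific_variants(clean_sim.callset_a, clean_sim.callset_b)
        table = tally_table(sa, sb)
        assert list(table.columns) == [
            "strain", "variant_type", "variants", "homozygous",
            "strain_specific", "strain_specific_pct"]
        assert len(table) == 4
        for row in table.itertuples(index=False):
            assert row.strain_specific <= row.homozygous <= row.variants
            assert row.strain_specific_pct == specific_percentage(
                row.strain_specific, row.homozygous)
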