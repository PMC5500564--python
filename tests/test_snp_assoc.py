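"""Core statistic: calculated effects, t approximation, discovery, clustering."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from popeqtl import datasets
from popeqtl.simulate import GenotypeMatrix
from popeqtl.snp_assoc import (
    TTestContext,
    allele_frequency,
    calculated_effect_size,
    cluster_by_proximity,
    discover_candidates,
    distance_to_gene,
    min_effect_threshold,
    t_approximation,
    tss_distance_kb,
    validate_candidates,
)

CTX = TTestContext(n1=552, n2=138, alpha=0.01)


def _geno(dosage_rows, sample_ids):
    snps = [f"s{i}" for i in range(len(dosage_rows))]
    d = pd.DataFrame(dosage_rows, index=pd.Index(snps, name="snp_id"), columns=sample_ids)
    pos = pd.DataFrame({"chrom": "22", "pos": range(100, 100 + len(snps))}, index=d.index)
    return GenotypeMatrix(dosages=d, positions=pos)


class TestAlleleFrequency:
    def test_direct_allele_count(self):
        g = _geno([[0, 1, 2, 2]], ["a", "b", "c", "d"])
        f = allele_frequency(g, ["a", "b", "c", "d"])
        assert f["s0"] == pytest.approx(5 / 8)

    @pytest.mark.parametrize("dos,expect", [([0, 0, 0], 0.0), ([2, 2, 2], 1.0)])
    def test_degenerate(self, dos, expect):
        g = _geno([dos], ["a", "b", "c"])
        assert allele_frequency(g, ["a", "b", "c"])["s0"] == expect

    def test_missing_genotypes_excluded(self):
        g = _geno([[2, -1, 0, -1]], ["a", "b", "c", "d"])
        assert allele_frequency(g, ["a", "b", "c", "d"])["s0"] == pytest.approx(0.5)

    def test_all_missing_snp_dropped(self, caplog):
        g = _geno([[1, 1], [-1, -1]], ["a", "b"])
        with caplog.at_level("WARNING"):
            f = allele_frequency(g, ["a", "b"])
        assert "s1" not in f.index and "s0" in f.index

    def test_empty_member_list_rejected(self):
        g = _geno([[1]], ["a"])
        with pytest.raises(ValueError):
            allele_frequency(g, [])


class TestCalculatedEffect:
    @pytest.mark.parametrize(
        "beta,f1,f2,expected",
        [
            (0.53, 0.97, 0.54, 0.2279),
            (0.52, 0.70, 0.21, 0.2548),
            (0.52, 0.97, 0.54, 0.2236),
            (0.52, 0.69, 0.21, 0.2496),
            (0.52, 0.68, 0.21, 0.2444),
        ],
    )
    def test_worked_values(self, beta, f1, f2, expected):
        assert calculated_effect_size(beta, f1, f2) == pytest.approx(expected, abs=5e-5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.floats(-2, 2, allow_nan=False),
        st.floats(0, 1, allow_nan=False),
        st.floats(0, 1, allow_nan=False),
    )
    def test_antisymmetry(self, beta, f1, f2):
        assert calculated_effect_size(beta, f1, f2) == pytest.approx(-calculated_effect_size(beta, f2, f1))

    def test_frequency_range_enforced(self):
        with pytest.raises(ValueError):
            calculated_effect_size(0.5, 1.2, 0.1)


class TestTApproximation:
    def test_reaches_normal_critical_value(self):
        # 0.2214 is z_{0.99} * sqrt(1/552 + 1/138) by construction
        assert t_approximation(0.2214, CTX) == pytest.approx(2.3263, abs=5e-4)

    def test_zero_maps_to_zero(self):
        assert t_approximation(0.0, CTX) == 0.0

    def test_equal_minimal_samples_unit_scale(self):
        ctx = TTestContext(n1=2, n2=2)
        assert t_approximation(0.37, ctx) == pytest.approx(0.37)


class TestMinEffectThreshold:
    def test_reference_cohort_threshold_rounds_to_022(self):
        assert round(min_effect_threshold(CTX), 2) == 0.22

    def test_two_sided_is_larger(self):
        two = min_effect_threshold(TTestContext(n1=552, n2=138, alpha=0.01, sidedness="two-sided"))
        assert round(two, 2) == 0.25

    def test_scaling_law(self):
        base = min_effect_threshold(CTX)
        doubled = min_effect_threshold(TTestContext(n1=1104, n2=276, alpha=0.01))
        assert doubled == pytest.approx(base / math.sqrt(2))

    def test_vanishes_for_large_samples(self):
        big = min_effect_threshold(TTestContext(n1=10**9, n2=10**9, alpha=0.01))
        assert big < 1e-3

    def test_student_t_reference_slightly_larger(self):
        t_ref = min_effect_threshold(TTestContext(n1=20, n2=20, alpha=0.01, reference="t"))
        z_ref = min_effect_threshold(TTestContext(n1=20, n2=20, alpha=0.01, reference="normal"))
        assert t_ref > z_ref


class TestDiscovery:
    def test_worked_example_all_six_returned(self):
        cands = discover_candidates(datasets.cyp2d6_eqtls(), datasets.cyp2d6_frequencies(), CTX, "AA", "CA", 1)
        assert len(cands) == 6
        effects = sorted(round(c.calculated_effect, 4) for c in cands)
        assert effects == sorted([0.2279, 0.2236, 0.2279, 0.2548, 0.2496, 0.2444])
        # sorted by |effect| descending
        mags = [abs(c.calculated_effect) for c in cands]
        assert mags == sorted(mags, reverse=True)

    def test_opposite_observed_sign_empties_list(self):
        cands = discover_candidates(datasets.cyp2d6_eqtls(), datasets.cyp2d6_frequencies(), CTX, "AA", "CA", -1)
        assert cands == []

    def test_equal_frequencies_excluded(self):
        eq = pd.DataFrame([dict(snp_id="s1", chrom="22", pos=100, gene_id="g", effect_size=0.53, pvalue=1e-4)])
        fr = pd.DataFrame({"AA": [0.5], "CA": [0.5]}, index=pd.Index(["s1"], name="snp_id"))
        assert discover_candidates(eq, fr, CTX, "AA", "CA", 1) == []

    def test_eqtl_pvalue_prefilter(self):
        eq = datasets.cyp2d6_eqtls().copy()
        eq.loc[0, "pvalue"] = 0.5
        cands = discover_candidates(eq, datasets.cyp2d6_frequencies(), CTX, "AA", "CA", 1)
        assert len(cands) == 5
        cands = discover_candidates(eq, datasets.cyp2d6_frequencies(), CTX, "AA", "CA", 1, eqtl_p_max=None)
        assert len(cands) == 6

    def test_missing_frequency_skipped(self, caplog):
        eq = datasets.cyp2d6_eqtls()
        fr = datasets.cyp2d6_frequencies().drop(index="rs72452")
        with caplog.at_level("WARNING"):
            cands = discover_candidates(eq, fr, CTX, "AA", "CA", 1)
        assert len(cands) == 5

    def test_matches_brute_force_filter_on_random_tables(self):
        """Discovery = {records: |beta*(f1-f2)| >= threshold and sign matches}."""
        rng = np.random.default_rng(11)
        thr = min_effect_threshold(CTX)
        for _ in range(100):
            n = int(rng.integers(1, 30))
            snps = [f"s{i}" for i in range(n)]
            eq = pd.DataFrame(
                dict(
                    snp_id=snps,
                    chrom="1",
                    pos=rng.integers(1, 10**6, size=n),
                    gene_id="g",
                    effect_size=rng.uniform(-1, 1, size=n),
                    pvalue=rng.uniform(1e-6, 0.009, size=n),
                )
            )
            fr = pd.DataFrame(
                {"AA": rng.uniform(0, 1, size=n), "CA": rng.uniform(0, 1, size=n)},
                index=pd.Index(snps, name="snp_id"),
            )
            sign = int(rng.choice([1, -1]))
            got = {c.snp_id for c in discover_candidates(eq, fr, CTX, "AA", "CA", sign)}
            expect = set()
            for s, b in zip(snps, eq["effect_size"]):
                d = b * (fr.loc[s, "AA"] - fr.loc[s, "CA"])
                if abs(d) >= thr and d != 0 and (1 if d > 0 else -1) == sign:
                    expect.add(s)
            assert got == expect

    def test_antisymmetric_in_population_order(self):
        c1 = discover_candidates(datasets.cyp2d6_eqtls(), datasets.cyp2d6_frequencies(), CTX, "AA", "CA", 1)
        c2 = discover_candidates(datasets.cyp2d6_eqtls(), datasets.cyp2d6_frequencies(), CTX, "CA", "AA", -1)
        assert {c.snp_id for c in c1} == {c.snp_id for c in c2}
        e1 = {c.snp_id: c.calculated_effect for c in c1}
        for c in c2:
            assert c.calculated_effect == pytest.approx(-e1[c.snp_id])


class TestValidation:
    def test_held_out_population_confirms_worked_example(self):
        cands = discover_candidates(datasets.cyp2d6_eqtls(), datasets.cyp2d6_frequencies(), CTX, "AA", "CA", 1)
        cands = validate_candidates(cands, datasets.cyp2d6_frequencies(), "AA", "AS", 1)
        assert all(c.validated for c in cands)
        rs = {c.snp_id: c for c in cands}
        # rs72452: 0.53 * (0.97 - 0.61) = 0.1908 > 0, matching the observed direction
        assert rs["rs72452"].beta * (0.97 - 0.61) == pytest.approx(0.1908)

    def test_zero_predicted_effect_not_validated(self):
        cands = discover_candidates(datasets.cyp2d6_eqtls(), datasets.cyp2d6_frequencies(), CTX, "AA", "CA", 1)
        fr = datasets.cyp2d6_frequencies().copy()
        fr["AS"] = fr["AA"]
        cands = validate_candidates(cands, fr, "AA", "AS", 1)
        assert all(c.validated is False for c in cands)

    def test_opposite_sign_not_validated(self):
        cands = discover_candidates(datasets.cyp2d6_eqtls(), datasets.cyp2d6_frequencies(), CTX, "AA", "CA", 1)
        cands = validate_candidates(cands, datasets.cyp2d6_frequencies(), "AA", "AS", -1)
        assert all(c.validated is False for c in cands)

    def test_missing_validation_frequency_is_unknown(self, caplog):
        cands = discover_candidates(datasets.cyp2d6_eqtls(), datasets.cyp2d6_frequencies(), CTX, "AA", "CA", 1)
        fr = datasets.cyp2d6_frequencies().copy()
        fr.loc["rs72452", "AS"] = np.nan
        with caplog.at_level("WARNING"):
            cands = validate_candidates(cands, fr, "AA", "AS", 1)
        status = {c.snp_id: c.validated for c in cands}
        assert status["rs72452"] is None
        assert status["rs714002"] is True


class TestClustering:
    def test_worked_example_two_clusters_of_three(self):
        cands = discover_candidates(datasets.cyp2d6_eqtls(), datasets.cyp2d6_frequencies(), CTX, "AA", "CA", 1)
        cands = cluster_by_proximity(cands)
        by_cluster = {}
        for c in cands:
            by_cluster.setdefault(c.cluster_id, []).append(c.snp_id)
        assert len(by_cluster) == 2
        assert sorted(len(v) for v in by_cluster.values()) == [3, 3]
        assert set(by_cluster[1]) == {"rs72452", "rs5751220", "rs6002626"}
        assert set(by_cluster[2]) == {"rs714002", "rs713811", "rs2011944"}

    def test_singleton(self):
        cands = discover_candidates(datasets.cyp2d6_eqtls().head(1), datasets.cyp2d6_frequencies(), CTX, "AA", "CA", 1)
        assert [c.cluster_id for c in cluster_by_proximity(cands)] == [1]

    def test_gap_boundary_inclusive(self):
        from popeqtl.snp_assoc import CandidateSNP

        def mk(pos):
            return CandidateSNP("s", "1", pos, "g", 0.5, {}, 0.3, 3.0, True, True)

        same = cluster_by_proximity([mk(1000), mk(41_000)], max_gap_bp=40_000)
        assert same[0].cluster_id == same[1].cluster_id
        split = cluster_by_proximity([mk(1000), mk(41_001)], max_gap_bp=40_000)
        assert split[0].cluster_id != split[1].cluster_id

    def test_chromosomes_never_merge(self):
        from popeqtl.snp_assoc import CandidateSNP

        a = CandidateSNP("s1", "1", 100, "g", 0.5, {}, 0.3, 3.0, True, True)
        b = CandidateSNP("s2", "2", 150, "g", 0.5, {}, 0.3, 3.0, True, True)
        out = cluster_by_proximity([a, b])
        assert out[0].cluster_id != out[1].cluster_id


class TestDistances:
    GENE = datasets.CYP2D6_GENE

    def test_downstream_snp_distances(self):
        assert distance_to_gene(42_481_849, self.GENE["start"], self.GENE["end"]) == 42_481_849 - 42_130_906
        assert tss_distance_kb(42_481_849, self.GENE["start"]) == 355

    def test_inside_and_boundary(self):
        assert distance_to_gene(42_128_000, self.GENE["start"], self.GENE["end"]) == 0
        assert distance_to_gene(self.GENE["start"], self.GENE["start"], self.GENE["end"]) == 0

    def test_upstream_distance(self):
        assert distance_to_gene(42_126_000, self.GENE["start"], self.GENE["end"]) == 499

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            distance_to_gene(5, 10, 2)
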