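"""Pseudo-haploid kinship: mismatch, jackknife, estimator, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from matrikin import relatedness as rel
from matrikin import synthetic_data as synth
from matrikin.relatedness import RelatednessError
from matrikin.synthetic_data import SimReadParams


def _calls(rows):
    return pd.DataFrame(rows, columns=["individual", "chrom", "pos", "base"])


class TestExcludeCpg:
    def test_identity_when_unflagged(self):
        t = pd.DataFrame({"chrom": [1, 2], "pos": [10, 20],
                          "cpg": [False, False], "base": ["A", "C"]})
        out = rel.exclude_cpg(t)
        assert len(out) == 2

    def test_flagged_fraction_removed(self):
        t = pd.DataFrame({"chrom": [1] * 100, "pos": range(100),
                          "cpg": [True] * 20 + [False] * 80,
                          "base": ["A"] * 100})
        assert len(rel.exclude_cpg(t)) == 80

    def test_non_autosomes_removed(self):
        t = pd.DataFrame({"chrom": ["1", "22", "X", "23"],
                          "pos": [1, 2, 3, 4],
                          "cpg": [False] * 4, "base": list("ACGT")})
        out = rel.exclude_cpg(t)
        assert list(out["chrom"]) == ["1", "22"]


class TestPseudoHaploidize:
    def test_single_read_sites_deterministic(self):
        t = pd.DataFrame({"individual": ["a"] * 3, "chrom": [1, 1, 2],
                          "pos": [10, 20, 10], "base": ["A", "C", "G"]})
        out = rel.pseudo_haploidize(t, seed=0)
        assert list(out["base"]) == ["A", "C", "G"]

    def test_heterozygous_site_resampled_evenly(self):
        """Over many seeds, each read at a 2-read site is drawn ~50%."""
        t = pd.DataFrame({"individual": ["a", "a"], "chrom": [1, 1],
                          "pos": [10, 10], "base": ["A", "C"]})
        n = 400
        picks = sum(rel.pseudo_haploidize(t, seed=s)["base"].iloc[0] == "A"
                    for s in range(n))
        se = np.sqrt(0.25 / n)
        assert abs(picks / n - 0.5) < 3 * se

    def test_different_seeds_same_site_support(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame({"individual": ["a"] * 200,
                          "chrom": rng.integers(1, 3, 200),
                          "pos": rng.integers(1, 50, 200),
                          "base": rng.choice(list("ACGT"), 200)})
        a = rel.pseudo_haploidize(t, seed=1)
        b = rel.pseudo_haploidize(t, seed=2)
        assert set(map(tuple, a[["chrom", "pos"]].values)) == \
               set(map(tuple, b[["chrom", "pos"]].values))
        assert not a["base"].equals(b["base"])


class TestPairwiseMismatch:
    def test_identical_call_sets_zero(self):
        a = _calls([["a", 1, i, "A"] for i in range(10)])
        b = _calls([["b", 1, i, "A"] for i in range(10)])
        x, n, _ = rel.pairwise_mismatch(a, b)
        assert x == 0.0 and n == 10

    def test_toy_count(self):
        a = _calls([["a", 1, i, "A"] for i in range(10)])
        bases = ["C", "C"] + ["A"] * 8
        b = _calls([["b", 1, i, bases[i]] for i in range(10)])
        x, n, _ = rel.pairwise_mismatch(a, b)
        assert x == pytest.approx(0.2) and n == 10

    def test_intersection_only(self):
        a = _calls([["a", 1, 1, "A"], ["a", 1, 2, "A"]])
        b = _calls([["b", 1, 2, "C"], ["b", 1, 3, "C"]])
        x, n, _ = rel.pairwise_mismatch(a, b)
        assert n == 1 and x == 1.0

    def test_empty_intersection_rejected(self):
        a = _calls([["a", 1, 1, "A"]])
        b = _calls([["b", 2, 1, "C"]])
        with pytest.raises(RelatednessError):
            rel.pairwise_mismatch(a, b)


class TestBlockJackknife:
    def test_equal_block_means_zero_se(self):
        se = rel.block_jackknife_se(np.array([0.2, 0.2, 0.2]),
                                    np.array([100, 200, 50]))
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_two_equal_blocks_closed_form(self):
        """Two equal-weight blocks with means 0.1/0.3: delete-one estimates
        are 0.3/0.1, giving SE = 0.1 by the standard jackknife."""
        se = rel.block_jackknife_se(np.array([0.1, 0.3]), np.array([500, 500]))
        assert se == pytest.approx(0.1)

    def test_equal_weights_reduce_to_unweighted(self):
        rng = np.random.default_rng(2)
        m = rng.uniform(0.1, 0.4, 12)
        w = np.full(12, 250.0)
        se = rel.block_jackknife_se(m, w)
        g = len(m)
        theta_del = np.array([np.delete(m, j).mean() for j in range(g)])
        var = (g - 1) / g * ((theta_del - theta_del.mean()) ** 2).sum()
        assert se == pytest.approx(np.sqrt(var))

    def test_single_block_rejected(self):
        with pytest.raises(RelatednessError):
            rel.block_jackknife_se(np.array([0.1]), np.array([10]))

    def test_se_tracks_empirical_sd(self):
        """Jackknife SE within a factor 1.5 of the empirical SD of x over
        replicate simulations of an unrelated pair."""
        ped = synth.PedigreeSpec(("A", "B"))
        xs, ses = [], []
        for r in range(40):
            gt = synth.simulate_pedigree(ped, 8_000, seed=500 + r)
            reads = synth.sample_snp_reads(
                gt, SimReadParams(coverage=1.0, error=0.0, seed=600 + r))
            calls = rel.pseudo_haploidize(rel.exclude_cpg(reads), seed=700 + r)
            by = {i: g for i, g in calls.groupby("individual")}
            x, _, blocks = rel.pairwise_mismatch(by["A"], by["B"])
            xs.append(x)
            ses.append(rel.block_jackknife_se(blocks["x"].to_numpy(),
                                              blocks["n_sites"].to_numpy()))
        ratio = np.mean(ses) / np.std(xs, ddof=1)
        assert 1 / 1.5 < ratio < 1.5


class TestEstimateR:
    @pytest.mark.parametrize("x,expected", [
        (0.21, 0.0),      # unrelated boundary: x = 2b
        (0.105, 1.0),     # identical-individuals boundary: x = b
        (0.1575, 0.5),    # midpoint
    ])
    def test_boundary_conditions(self, x, expected):
        r, _ = rel.estimate_r(x, b=0.105)
        assert r == pytest.approx(expected)

    def test_ci_propagation(self):
        r, (lo, hi) = rel.estimate_r(0.1575, se_x=0.0105, b=0.105)
        assert hi - r == pytest.approx(1.96 * 0.0105 / 0.105)
        assert r - lo == pytest.approx(hi - r)

    @given(st.floats(0.01, 0.4), st.floats(0.01, 0.4), st.floats(0.02, 0.3))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_affine_and_strictly_decreasing(self, x1, x2, b):
        r1, _ = rel.estimate_r(x1, b=b)
        r2, _ = rel.estimate_r(x2, b=b)
        mid, _ = rel.estimate_r((x1 + x2) / 2, b=b)
        assert mid == pytest.approx((r1 + r2) / 2, rel=1e-9, abs=1e-9)
        if x1 < x2:
            assert r1 > r2

    def test_nonpositive_b_rejected(self):
        with pytest.raises(RelatednessError):
            rel.estimate_r(0.2, b=0.0)

    def test_expected_b_from_frequencies(self):
        p = np.array([0.5, 0.1, 0.9])
        assert rel.expected_b(p) == pytest.approx((0.25 + 0.09 + 0.09) / 3)


class TestDetectRelated:
    def test_zero_at_baseline(self):
        assert rel.detect_related(0.21, 0.01) == 0.0

    def test_four_se_below_baseline(self):
        z = rel.detect_related(0.21 - 4 * 0.01, 0.01)
        assert z == pytest.approx(4.0)

    def test_zero_se_at_baseline_defined(self):
        assert rel.detect_related(0.21, 0.0) == 0.0
        with pytest.raises(RelatednessError):
            rel.detect_related(0.20, 0.0)

    def test_unrelated_false_positive_rate(self):
        """Unrelated pairs cross Z>3 in at most ~1% of replicates."""
        rng = np.random.default_rng(9)
        ped = synth.PedigreeSpec(("A", "B"))
        flagged = 0
        n_rep = 200
        for r in range(n_rep):
            gt = synth.simulate_pedigree(ped, 4_000, seed=2000 + r)
            reads = synth.sample_snp_reads(
                gt, SimReadParams(coverage=1.0, error=0.0, seed=3000 + r))
            calls = rel.pseudo_haploidize(rel.exclude_cpg(reads), seed=4000 + r)
            by = {i: g for i, g in calls.groupby("individual")}
            x, _, blocks = rel.pairwise_mismatch(by["A"], by["B"])
            se = rel.block_jackknife_se(blocks["x"].to_numpy(),
                                        blocks["n_sites"].to_numpy())
            b = rel.expected_b(gt.sites.loc[~gt.sites["cpg"], "freq"].to_numpy())
            if rel.detect_related(x, se, b=b) > 3:
                flagged += 1
        # one-sided normal tail at 3 is 0.13%; allow binomial slack to ~2.5%
        assert flagged <= 5


class TestClassifyDegree:
    @pytest.mark.parametrize("r,ci,expected", [
        (0.5, (0.4, 0.6), "first"),
        (0.35, (0.2, 0.55), "first-or-second"),
        (0.02, (-0.05, 0.1), "unrelated"),
        (1.0, (0.9, 1.1), "identical"),
        (0.25, (0.15, 0.35), "second"),
        (0.5, (-0.1, 1.1), "ambiguous"),   # all four canonical values inside
        (0.6, (0.55, 0.65), "ambiguous"),  # none inside
    ])
    def test_labels(self, r, ci, expected):
        assert rel.classify_degree(r, ci) == expected


class TestKinTable:
    def test_duplicate_sample_b_self_consistency(self, three_generations):
        """x between duplicate samples of one individual is within 3 SE of
        half the unrelated-pair mismatch."""
        gt = synth.simulate_pedigree(three_generations, 40_000, seed=61)
        gt.genotypes.loc["U1dup"] = gt.genotypes.loc["U1"]
        reads = synth.sample_snp_reads(
            gt, SimReadParams(coverage=1.0, error=0.0, seed=62))
        calls = rel.pseudo_haploidize(rel.exclude_cpg(reads), seed=63)
        by = {i: g for i, g in calls.groupby("individual")}
        x_dup, n_dup, _ = rel.pairwise_mismatch(by["U1"], by["U1dup"])
        x_unrel, n_unrel, _ = rel.pairwise_mismatch(by["U1"], by["U2"])
        se = np.sqrt(x_dup * (1 - x_dup) / n_dup
                     + x_unrel * (1 - x_unrel) / (4 * n_unrel))
        assert abs(x_dup - x_unrel / 2) < 3 * se

    def test_grandmother_grandson_recovery(self, three_generations):
        """CI contains 0.25 in >=90% of replicates at ~20k overlapping sites."""
        hits = 0
        n_rep = 20
        for r in range(n_rep):
            gt = synth.simulate_pedigree(three_generations, 55_000, seed=800 + r)
            reads = synth.sample_snp_reads(
                gt, SimReadParams(coverage=1.0, error=0.001, seed=900 + r))
            b = rel.expected_b(gt.sites.loc[~gt.sites["cpg"], "freq"].to_numpy())
            calls = rel.pseudo_haploidize(rel.exclude_cpg(reads), seed=1000 + r)
            by = {i: g for i, g in calls.groupby("individual")}
            est = rel.kin_pair(by["GM"], by["SON"], ("GM", "SON"), b=b)
            if est.ci95_r[0] <= 0.25 <= est.ci95_r[1]:
                hits += 1
        assert hits >= 0.9 * n_rep

    def test_table_shape_and_derived_b(self, three_generations):
        gt = synth.simulate_pedigree(three_generations, 10_000, seed=71)
        reads = synth.sample_snp_reads(
            gt, SimReadParams(coverage=0.8, error=0.001, seed=72))
        out = rel.kin_table(reads, seed=73, b=None)
        n = len(three_generations.individuals)
        assert len(out) == n * (n - 1) // 2
        # derived b is half the maximum observed mismatch
        assert out["b"].iloc[0] == pytest.approx(out["x"].max() / 2)
        assert {"n_sites", "x", "se_x", "r", "z", "degree"} <= set(out.columns)
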