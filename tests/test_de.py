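"""Differential-expression engine: size factors, dispersions, Wald test,
shrinkage, transform and Venn overlap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hybridexpr import SimConfig, simulate_counts
from hybridexpr import de as de_mod


def _frame(rows, columns=None):
    rows = np.asarray(rows)
    return pd.DataFrame(rows,
                        index=[f"g{i}" for i in range(rows.shape[0])],
                        columns=columns or [f"s{j}" for j in range(rows.shape[1])])


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = _frame([[10, 10], [3, 3]])
        np.testing.assert_allclose(de_mod.size_factors(counts), [1.0, 1.0])

    def test_median_of_ratios_hand_example(self):
        counts = _frame([[10, 20], [30, 60]])
        np.testing.assert_allclose(de_mod.size_factors(counts),
                                   [1 / np.sqrt(2), np.sqrt(2)], atol=1e-12)

    def test_zero_containing_gene_excluded(self):
        counts = _frame([[0, 5], [10, 10]])
        np.testing.assert_allclose(de_mod.size_factors(counts), [1.0, 1.0])

    def test_no_reference_gene_errors_and_fallback_works(self):
        counts = _frame([[0, 5], [10, 0]])
        with pytest.raises(ValueError, match="pseudo"):
            de_mod.size_factors(counts)
        sf = de_mod.size_factors(counts, pseudo_reference=True)
        assert (sf > 0).all()

    def test_scaling_one_sample_scales_factor_ratios(self, rng):
        """Tripling one library triples its size factor relative to every
        other sample (absolute factors shift by the common geometric-mean
        term, which normalization cancels)."""
        counts = _frame(rng.poisson(100, (50, 4)))
        sf = de_mod.size_factors(counts)
        scaled = counts.copy()
        scaled["s2"] *= 3
        sf2 = de_mod.size_factors(scaled)
        ratio = (sf2 / sf) / (sf2["s0"] / sf["s0"])
        np.testing.assert_allclose(ratio["s2"], 3.0, rtol=1e-12)
        np.testing.assert_allclose(ratio.drop("s2"), 1.0, rtol=1e-12)


class TestDispersions:
    def test_poisson_counts_give_near_zero_dispersion(self, rng):
        mu = rng.uniform(20, 200, 5000)
        counts = _frame(rng.poisson(mu[:, None], (5000, 10)))
        design = pd.Series(["a"] * 5 + ["b"] * 5, index=counts.columns)
        sf = de_mod.size_factors(counts, pseudo_reference=True)
        phi = de_mod.estimate_dispersions(counts, sf, design)
        assert np.median(phi) < 0.05

    def test_recovers_true_dispersion(self, rng):
        mu, alpha = 100.0, 0.1
        lam = rng.gamma(1 / alpha, alpha * mu, (5000, 10))
        counts = _frame(rng.poisson(lam))
        design = pd.Series(["a"] * 5 + ["b"] * 5, index=counts.columns)
        sf = de_mod.size_factors(counts, pseudo_reference=True)
        phi = de_mod.estimate_dispersions(counts, sf, design)
        assert 0.07 < np.median(phi) < 0.13

    def test_constant_counts_fall_to_trend_floor(self):
        counts = _frame(np.full((20, 6), 50))
        design = pd.Series(["a"] * 3 + ["b"] * 3, index=counts.columns)
        sf = de_mod.size_factors(counts)
        phi = de_mod.estimate_dispersions(counts, sf, design)
        assert (phi > 0).all() and (phi < 1e-3).all()


class TestWaldTest:
    def test_identical_groups_give_zero_lfc_unit_p(self):
        block = np.array([[12, 30, 7], [100, 80, 90], [5, 5, 5]])
        counts = _frame(np.hstack([block, block]))
        design = pd.Series(["a"] * 3 + ["b"] * 3, index=counts.columns)
        sf = pd.Series(1.0, index=counts.columns)
        phi = pd.Series(0.05, index=counts.index)
        res = de_mod.wald_test(counts, sf, phi, design, ("a", "b"))
        np.testing.assert_allclose(res["lfc"], 0.0, atol=1e-8)
        np.testing.assert_allclose(res["p"], 1.0, atol=1e-8)

    def test_null_calibration_and_uniform_p(self):
        cfg = SimConfig(n_genes=2000, n_tissues=1, mode_fractions={}, seed=7)
        counts, samples, _ = simulate_counts(cfg)
        block = samples[samples.species != "hybrid"]
        sub = counts[block["sample"]]
        design = block.set_index("sample")["species"]
        sf = de_mod.size_factors(sub)
        phi = de_mod.estimate_dispersions(sub, sf, design)
        res = de_mod.wald_test(sub, sf, phi, design, ("collared", "pied"))
        rate = (res["p"] < 0.05).mean()
        half_width = 1.96 * np.sqrt(0.05 * 0.95 / len(res))
        assert abs(rate - 0.05) < half_width
        assert stats.kstest(res["p"].dropna(), "uniform").pvalue > 0.01

    def test_power_on_planted_two_log2_units(self, rng):
        cfg = SimConfig(n_genes=600, n_tissues=1, base_log2_range=(7, 10),
                        mode_fractions={"additive": 0.3},
                        effect_size_log2=2.0, seed=3)
        counts, samples, truth = simulate_counts(cfg)
        block = samples[samples.species != "hybrid"]
        sub = counts[block["sample"]]
        design = block.set_index("sample")["species"]
        sf = de_mod.size_factors(sub)
        phi = de_mod.estimate_dispersions(sub, sf, design)
        res = de_mod.wald_test(sub, sf, phi, design, ("collared", "pied"))
        planted = truth.gene_tissue.set_index("gene")["true_lfc"] \
            .loc[res.index].abs() > 0
        assert (res.loc[planted.to_numpy(), "padj"] < 0.05).mean() >= 0.95

    def test_all_zero_gene_untested(self):
        counts = _frame([[0, 0, 0, 0], [10, 12, 9, 11]])
        design = pd.Series(["a", "a", "b", "b"], index=counts.columns)
        sf = pd.Series(1.0, index=counts.columns)
        phi = pd.Series(0.01, index=counts.index)
        res = de_mod.wald_test(counts, sf, phi, design, ("a", "b"))
        assert res.loc["g0", "status"] == "untested"
        assert np.isnan(res.loc["g0", "p"])
        assert res.loc["g1", "status"] == "nDE"

    def test_uniform_depth_scaling_leaves_lfc_invariant(self, rng):
        """Scaling every library by the same constant leaves every fold
        change unchanged; scaling a single library moves fold changes only
        within sampling-noise order."""
        counts = _frame(rng.poisson(200, (100, 6)))
        design = pd.Series(["a"] * 3 + ["b"] * 3, index=counts.columns)
        phi0 = pd.Series(0.0, index=counts.index)
        sf = de_mod.size_factors(counts)
        res1 = de_mod.wald_test(counts, sf, phi0, design, ("a", "b"))
        uniform = counts * 4
        res2 = de_mod.wald_test(uniform, de_mod.size_factors(uniform), phi0,
                                design, ("a", "b"))
        np.testing.assert_allclose(res1["lfc"], res2["lfc"], atol=1e-8)
        phi = pd.Series(0.02, index=counts.index)
        res1 = de_mod.wald_test(counts, sf, phi, design, ("a", "b"))
        single = counts.copy()
        single["s0"] *= 4
        res3 = de_mod.wald_test(single, de_mod.size_factors(single), phi,
                                design, ("a", "b"))
        assert np.abs(res3["lfc"] - res1["lfc"]).max() < 0.1


class TestShrinkage:
    def test_zero_counts_shrink_to_zero(self):
        counts = _frame([[0, 0, 0, 0], [50, 60, 40, 55]])
        design = pd.Series(["a", "a", "b", "b"], index=counts.columns)
        sf = pd.Series(1.0, index=counts.columns)
        phi = pd.Series(0.05, index=counts.index)
        res = de_mod.wald_test(counts, sf, phi, design, ("a", "b"))
        shr = de_mod.shrink_lfc(counts, sf, phi, design, ("a", "b"), res,
                                prior_var=1.0)
        assert shr["g0"] == 0.0

    def test_low_coverage_gene_shrunk_more(self):
        # same raw 2-fold change, 5x apart in coverage
        counts = _frame([[20, 20, 10, 10], [100, 100, 50, 50]])
        design = pd.Series(["a", "a", "b", "b"], index=counts.columns)
        sf = pd.Series(1.0, index=counts.columns)
        phi = pd.Series(0.05, index=counts.index)
        res = de_mod.wald_test(counts, sf, phi, design, ("a", "b"))
        shr = de_mod.shrink_lfc(counts, sf, phi, design, ("a", "b"), res,
                                prior_var=0.25)
        assert abs(shr["g0"]) < abs(shr["g1"])
        assert (shr.abs() <= res["lfc"].abs() + 1e-9).all()

    def test_infinite_prior_recovers_mle(self, parent_de):
        d = parent_de
        shr = de_mod.shrink_lfc(d["counts"], d["sf"], d["phi"], d["design"],
                                ("collared", "pied"), d["result"],
                                prior_var=1e12)
        tested = d["result"]["status"] != "untested"
        np.testing.assert_allclose(shr[tested], d["result"].loc[tested, "lfc"],
                                   atol=1e-6)


class TestTransformAndOverlap:
    def test_rlog_like_basic_values(self):
        counts = _frame([[0, 1], [3, 7]])
        sf = pd.Series(1.0, index=counts.columns)
        out = de_mod.rlog_like_transform(counts, sf)
        assert out.iloc[0, 0] == 0.0
        np.testing.assert_allclose(out.iloc[1, 1], np.log2(8))

    def test_rlog_like_depth_invariance_and_monotonicity(self):
        counts = _frame([[10, 20], [40, 80]])
        sf = pd.Series([1.0, 2.0], index=counts.columns)
        out = de_mod.rlog_like_transform(counts, sf)
        np.testing.assert_allclose(out["s0"], out["s1"])
        assert (out.diff().dropna() >= 0).all().all()

    def test_overlap_hand_example(self):
        sets = {"t1": {"a", "b"}, "t2": {"b", "c"}, "t3": {"b"}}
        cells = de_mod.de_overlap(sets, ["a", "b", "c", "d"])
        assert cells[frozenset({"t1", "t2", "t3"})] == 1  # gene b
        assert cells[frozenset({"t1"})] == 1              # gene a
        assert cells[frozenset({"t2"})] == 1              # gene c
        assert cells[frozenset()] == 1                    # gene d
        assert sum(cells.values()) == 4

    def test_overlap_disjoint_and_identical(self):
        disjoint = de_mod.de_overlap({"t1": {"a"}, "t2": {"b"}}, ["a", "b"])
        assert disjoint[frozenset({"t1", "t2"})] == 0
        same = de_mod.de_overlap({"t1": {"a"}, "t2": {"a"}}, ["a", "b"])
        assert same[frozenset({"t1", "t2"})] == 1
        assert same[frozenset({"t1"})] == same[frozenset({"t2"})] == 0

    def test_overlap_rejects_foreign_genes(self):
        with pytest.raises(ValueError, match="universe"):
            de_mod.de_overlap({"t1": {"x"}}, ["a"])
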