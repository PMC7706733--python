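"""Association battery: Mann-Whitney, chi-square, hypergeometric fast-Z,
compensation test and GLM determinants."""

import math

import numpy as np
import pandas as pd
import pytest

from hybridexpr import inference as inf


class TestMwuAssociation:
    def test_identical_multisets_tie_saturated(self):
        res = inf.mwu_association([1.0, 1.0, 1.0, 1.0],
                                  [True, True, False, False])
        assert res.p == 1.0
        assert res.direction == 0

    def test_exact_small_sample_hand_example(self):
        # x = {1,2,3} below y = {4,5,6}: U = 0, exact two-sided p = 0.1
        res = inf.mwu_association([1, 2, 3, 4, 5, 6],
                                  [True, True, True, False, False, False])
        assert res.statistic == 0.0
        assert res.p == pytest.approx(0.1)
        assert res.direction == -1

    def test_normal_approximation_matches_permutation_oracle(self, rng):
        x = rng.normal(0.3, 1, 30)
        y = rng.normal(0.0, 1, 30)
        values = np.concatenate([x, y])
        flags = np.array([True] * 30 + [False] * 30)
        res = inf.mwu_association(values, flags)
        from scipy.stats import rankdata
        ranks = rankdata(values)
        # vectorized label permutations: U = R1 - n1(n1+1)/2
        keys = rng.random((100_000, 60))
        perm_idx = np.argsort(keys, axis=1)[:, :30]
        r1 = ranks[perm_idx].sum(axis=1)
        u_perm = r1 - 30 * 31 / 2
        mu = 30 * 30 / 2
        p_perm = np.mean(np.abs(u_perm - mu) >= abs(res.statistic - mu) - 1e-9)
        assert abs(res.p - p_perm) < 0.005

    def test_empty_group_untestable(self):
        res = inf.mwu_association([1.0, 2.0], [True, True])
        assert math.isnan(res.p)
        assert "untestable" in res.note


class TestChisqYates:
    @pytest.mark.parametrize("table,expected,digits", [
        ([[5, 27], [81, 1542]], 2.25e-2, 4),
        ([[11, 40], [143, 1517]], 3.3e-3, 4),
        ([[11, 64], [141, 1505]], 1.07e-1, 3),
    ])
    def test_reproduces_published_two_by_two_p_values(self, table, expected,
                                                      digits):
        _, p = inf.chisq_yates(table)
        assert round(p, digits) == expected

    def test_balanced_table_null(self):
        stat, p = inf.chisq_yates([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    def test_zero_marginal_errors(self):
        with pytest.raises(ValueError, match="marginal"):
            inf.chisq_yates([[0, 0], [5, 5]])


def _hypergeom_brute(de_z, nde_z, de_a, nde_a):
    """Exact rational tail using integer binomial coefficients."""
    N = de_z + nde_z + de_a + nde_a
    K = de_z + de_a
    n = de_z + nde_z
    denom = math.comb(N, n)
    total = sum(math.comb(K, k) * math.comb(N - K, n - k)
                for k in range(de_z, min(K, n) + 1))
    return total / denom


class TestHypergeom:
    def test_zero_observed_gives_unit_p(self):
        assert inf.hypergeom_enrichment(0, 10, 5, 85) == pytest.approx(1.0)

    def test_small_table_matches_enumeration(self):
        p = inf.hypergeom_enrichment(2, 2, 2, 94)
        assert p == pytest.approx(_hypergeom_brute(2, 2, 2, 94), abs=1e-12)

    def test_random_tables_match_enumeration(self, rng):
        for _ in range(100):
            N = int(rng.integers(4, 201))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            k = int(rng.integers(max(0, K + n - N), min(K, n) + 1))
            p = inf.hypergeom_enrichment(k, n - k, K - k, N - K - n + k)
            assert p == pytest.approx(
                _hypergeom_brute(k, n - k, K - k, N - K - n + k), abs=1e-12)

    def test_monotone_in_observed_count(self):
        ps = [inf.hypergeom_enrichment(k, 20 - k, 30 - k, 50 + k)
              for k in range(0, 15)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            inf.hypergeom_enrichment(-1, 5, 5, 5)


class TestFastZ:
    def test_no_z_genes_untestable(self):
        out = inf.fast_z_test({"brain": (0, 0, 10, 90)})
        assert np.isnan(out.loc[0, "p"])

    def test_planted_enrichment_detected_with_holm(self):
        counts = {}
        for i, tissue in enumerate(["t1", "t2", "t3"]):
            counts[tissue] = (40, 460, 300, 11000)  # ~8% Z vs ~2.7% autosome
        out = inf.fast_z_test(counts)
        assert (out["p_holm"] < 0.05).all()

    def test_equal_rates_calibrated(self, rng):
        rejections = 0
        for rep in range(40):
            de_z = rng.binomial(500, 0.05)
            de_a = rng.binomial(10000, 0.05)
            p = inf.hypergeom_enrichment(de_z, 500 - de_z, de_a, 10000 - de_a)
            rejections += p < 0.05
        assert rejections <= 7


class TestCompensationTest:
    def _mis(self, eligible, mis):
        idx = [f"g{i}" for i in range(len(eligible))]
        return pd.DataFrame({"eligible": eligible, "misexpressed": mis,
                             "direction": "none"}, index=idx)

    def test_empty_margin_is_na(self):
        mis = self._mis([True] * 4, [False] * 4)
        ase = pd.Series(["ASE", "non-ASE", "ASE", "non-ASE"],
                        index=mis.index)
        chrom = pd.Series("autosome", index=mis.index)
        res = inf.compensation_test(mis, ase, chrom)
        assert math.isnan(res.p)
        assert "NA" in res.note

    def test_strong_association_detected(self, rng):
        n = 400
        mis_flag = np.arange(n) < 60
        ase_flag = np.where(mis_flag, rng.random(n) < 0.8,
                            rng.random(n) < 0.1)
        mis = self._mis([True] * n, mis_flag)
        ase = pd.Series(np.where(ase_flag, "ASE", "non-ASE"), index=mis.index)
        chrom = pd.Series("autosome", index=mis.index)
        res = inf.compensation_test(mis, ase, chrom)
        assert res.p < 1e-6
        assert res.direction == 1

    def test_independent_flags_calibrated(self, rng):
        rejections = 0
        for rep in range(40):
            n = 400
            mis_flag = rng.random(n) < 0.2
            ase_flag = rng.random(n) < 0.3
            mis = self._mis([True] * n, mis_flag)
            ase = pd.Series(np.where(ase_flag, "ASE", "non-ASE"),
                            index=mis.index)
            chrom = pd.Series("autosome", index=mis.index)
            res = inf.compensation_test(mis, ase, chrom)
            rejections += res.p < 0.05
        # Yates correction is conservative, so stay at or below nominal
        assert rejections <= 5


class TestGlmDeterminants:
    def _covariates(self, rng, n=2000):
        return pd.DataFrame({
            "ppi": rng.poisson(8, n).astype(float),
            "tau": rng.uniform(0, 1, n),
            "phi": rng.lognormal(-3, 0.5, n),
            "fst": rng.beta(2, 8, n),
        }, index=[f"g{i}" for i in range(n)])

    def test_planted_tau_effect_recovered(self, rng):
        hits = 0
        for rep in range(10):
            cov = self._covariates(rng, 5000)
            logit = -2.0 + 2.5 * (cov["tau"] - 0.5)
            y = rng.random(5000) < 1 / (1 + np.exp(-logit))
            fit = inf.glm_determinants(pd.Series(y.astype(float),
                                                 index=cov.index), cov)
            row = fit.set_index("covariate").loc["tau"]
            hits += (row["coef"] > 0) and (row["p"] < 0.05)
        assert hits >= 9

    def test_null_covariates_calibrated(self, rng):
        ps = []
        for rep in range(15):
            cov = self._covariates(rng, 800)
            y = (rng.random(800) < 0.2).astype(float)
            fit = inf.glm_determinants(pd.Series(y, index=cov.index), cov)
            ps.extend(fit["p"])
        assert 0.005 < np.mean(np.array(ps) < 0.05) < 0.15

    def test_linear_mode_matches_ols_oracle(self, rng):
        cov = self._covariates(rng, 500)
        y = 1.0 + 0.5 * ((cov["tau"] - cov["tau"].mean()) / cov["tau"].std(ddof=0)) \
            + rng.normal(0, 1, 500)
        fit = inf.glm_determinants(pd.Series(y.to_numpy(), index=cov.index),
                                   cov, mode="linear")
        import statsmodels.api as sm
        X = (cov - cov.mean()) / cov.std(ddof=0)
        oracle = sm.OLS(y.to_numpy(), sm.add_constant(X.to_numpy())).fit()
        np.testing.assert_allclose(fit["stat"], oracle.tvalues[1:], atol=1e-8)

    def test_degenerate_inputs_error(self, rng):
        cov = self._covariates(rng, 200)
        with pytest.raises(ValueError, match="constant"):
            inf.glm_determinants(
                pd.Series(0.0, index=cov.index), cov)
        with pytest.raises(ValueError, match="complete-case"):
            inf.glm_determinants(pd.Series(1.0, index=cov.index[:10]),
                                 cov.iloc[:10])
        constant = cov.assign(tau=1.0)
        with pytest.raises(ValueError, match="tau"):
            inf.glm_determinants(
                pd.Series(rng.integers(0, 2, 200).astype(float),
                          index=cov.index), constant)
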