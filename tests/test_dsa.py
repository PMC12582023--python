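"""Zero-inflated negative binomial abundance model and LRT."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from splicecov.design import SampleSheet, encode
from splicecov.dsa import (
    DsaConfig, ZinbParams, dsa_test, fit_dsa, run_dsa, size_factors,
    zinb_loglik,
)
from splicecov.dsa import testable_dsa as dsa_testability
from splicecov.junctions import CountMatrix


def design_for(n_per_group=10, covariates=False):
    rows = []
    for k, cond in enumerate(("control", "disease")):
        for i in range(n_per_group):
            r = {"sample_id": f"s{k}_{i}", "condition": cond}
            if covariates:
                r["sex"] = "M" if i % 2 else "F"
            rows.append(r)
    return encode(SampleSheet(pd.DataFrame(rows)), ["sex"] if covariates else [])


class TestZinbLoglik:
    def test_degenerate_all_zero_with_pi_one(self):
        d = design_for(2)
        params = ZinbParams(intercept=1.0, coefs=np.zeros(1), dispersion=2.0,
                            zero_prob=1.0)
        assert zinb_loglik(np.zeros(4), d, params) == 0.0

    def test_mixture_arithmetic_single_zero_observation(self):
        """y=0, pi=0.5 and NB(0)=0.2 gives log(0.5 + 0.5*0.2) = log 0.6."""
        d = design_for(1)
        # choose theta=1 (geometric): NB(0) = theta/(theta+m) = 0.2 -> m = 4
        params = ZinbParams(intercept=np.log(4.0), coefs=np.zeros(1),
                            dispersion=1.0, zero_prob=0.5)
        ll = zinb_loglik(np.array([0, 0]), d, params)
        assert ll == pytest.approx(2 * np.log(0.6), abs=1e-12)

    def test_poisson_limit_at_large_dispersion(self):
        """theta -> inf: NB collapses onto Poisson with the same mean."""
        d = design_for(3)
        y = np.array([3, 7, 0, 12, 5, 2])
        params = ZinbParams(intercept=np.log(5.0), coefs=np.array([0.3]),
                            dispersion=1e6, zero_prob=0.0)
        mean = params.mean(d.matrix)
        expected = stats.poisson.logpmf(y, mean).sum()
        assert zinb_loglik(y, d, params) == pytest.approx(expected, abs=1e-4)

    def test_nonfinite_parameter_rejected(self):
        d = design_for(1)
        params = ZinbParams(intercept=np.nan, coefs=np.zeros(1),
                            dispersion=1.0, zero_prob=0.0)
        with pytest.raises(ValueError, match="non-finite"):
            zinb_loglik(np.array([1, 2]), d, params)


class TestFit:
    def test_recovers_nb_mean_within_ten_percent(self, rng):
        d = design_for(100)  # N = 200
        y = rng.negative_binomial(5, 5 / (5 + 50), size=200)
        fit = fit_dsa(y, d, "null")
        assert fit.converged
        # null design is intercept-only here, baseline mean = exp(intercept)
        assert np.exp(fit.params.intercept) == pytest.approx(50, rel=0.10)

    def test_all_zero_counts_degenerate_pi(self):
        d = design_for(5)
        fit = fit_dsa(np.zeros(10, dtype=int), d, "null")
        assert fit.params.zero_prob > 0.9

    def test_nesting_alternative_at_least_null(self, rng):
        d = design_for(10)
        for _ in range(5):
            y = rng.negative_binomial(8, 8 / (8 + 30), size=20)
            f0 = fit_dsa(y, d, "null")
            f1 = fit_dsa(y, d, "alternative")
            assert f1.loglik >= f0.loglik - 1e-6

    def test_zero_inflation_estimated_when_present(self, rng):
        d = design_for(150)
        y = rng.negative_binomial(10, 10 / (10 + 80), size=300)
        y[rng.random(300) < 0.3] = 0
        fit = fit_dsa(y, d, "null")
        assert 0.15 < fit.params.zero_prob < 0.45

    def test_gridsearch_oracle_no_zeroinflation_no_covariates(self):
        """Brute-force NB(mean, theta) grid matches the optimizer's solution.

        Tiny 5-sample data, pure NB likelihood (prior effect checked to be
        small for this mu_hat), so a 2-D grid over (mean, theta) is a valid
        independent oracle for the fitted mean.
        """
        y = np.array([12, 15, 9, 14, 11])
        rows = [{"sample_id": f"s{i}", "condition": "c1" if i < 3 else "c2"}
                for i in range(5)]
        d = encode(SampleSheet(pd.DataFrame(rows)), [])
        fit = fit_dsa(y, d, "null", restarts=0)
        from splicecov.dsa import nb_logpmf

        means = np.linspace(5, 25, 401)
        thetas = np.geomspace(0.5, 500, 301)
        best = (-np.inf, None)
        mu_hat = y.mean()
        for th in thetas:
            for m in means:
                ll = nb_logpmf(y, np.full(5, m), th).sum()
                ll += -((m - mu_hat) ** 2) / (2 * mu_hat)  # same mean prior
                ll += -np.log(th) - np.log1p(th ** -4.0)  # same dispersion prior
                if ll > best[0]:
                    best = (ll, m)
        assert np.exp(fit.params.intercept) == pytest.approx(best[1], rel=0.02)


class TestLrt:
    def test_equal_logliks_give_p_one(self):
        from splicecov.dsa import FitResult

        f0 = FitResult(None, -10.0, -10.0, True, 5, "null", 4)
        f1 = FitResult(None, -10.0, -10.0, True, 5, "alternative", 5)
        lrt, df, p = dsa_test(f0, f1)
        assert (lrt, df, p) == (0.0, 1, 1.0)

    def test_chi_square_quantile(self):
        from splicecov.dsa import FitResult

        f0 = FitResult(None, -10.0, -10.0, True, 5, "null", 4)
        f1 = FitResult(None, -10.0 + 3.841 / 2, -10.0, True, 5, "alternative", 5)
        _, _, p = dsa_test(f0, f1)
        assert p == pytest.approx(0.05, abs=5e-4)

    def test_df_counted_from_free_parameters(self):
        from splicecov.dsa import FitResult

        f0 = FitResult(None, -10.0, -10.0, True, 5, "null", 4)
        f1 = FitResult(None, -8.0, -8.0, True, 5, "alternative", 6)
        _, df, _ = dsa_test(f0, f1)
        assert df == 2


class TestRunDsa:
    def simulate_matrix(self, rng, n_introns, n_shifted, d, fold=4.0):
        disease = d.samples_in("disease")
        rows, keys = [], []
        for j in range(n_introns):
            base = 40.0
            mean = np.where(disease & (j < n_shifted), base * fold, base)
            rows.append(rng.negative_binomial(10, 10 / (10 + mean)))
            keys.append(("chr1", 100 * j + 10, 100 * j + 90, "+"))
        df = pd.DataFrame(np.vstack(rows),
                          index=pd.Index(keys, tupleize_cols=False),
                          columns=d.sample_ids)
        return CountMatrix(df)

    def test_shifted_introns_rank_first(self, rng):
        d = design_for(10)
        m = self.simulate_matrix(rng, 10, 3, d)
        records = run_dsa(m, d)
        top3 = {r.intron_key for r in records[:3]}
        assert top3 == {("chr1", 10, 90, "+"), ("chr1", 110, 190, "+"),
                        ("chr1", 210, 290, "+")}
        assert all(records[i].p_value <= records[i + 1].p_value
                   for i in range(len(records) - 1))

    def test_empty_matrix_empty_result(self):
        d = design_for(3)
        m = CountMatrix(pd.DataFrame(np.zeros((0, 6), dtype=int),
                                     index=pd.Index([], tupleize_cols=False),
                                     columns=d.sample_ids))
        assert run_dsa(m, d) == []

    def test_label_permutation_rarely_significant(self, rng):
        """Permuting condition labels destroys the signal: q <= 0.05 calls
        should almost never appear across permutations."""
        d = design_for(10)
        m = self.simulate_matrix(rng, 12, 4, d)
        n_sig = []
        for _ in range(10):
            perm = rng.permutation(20)
            rows = [{"sample_id": sid, "condition": d.condition_labels[perm[i]]}
                    for i, sid in enumerate(d.sample_ids)]
            d_perm = encode(SampleSheet(pd.DataFrame(rows)), [])
            recs = run_dsa(m, d_perm)
            n_sig.append(sum(r.q_value <= 0.05 for r in recs))
        assert sum(n == 0 for n in n_sig) >= 8

    def test_condition_means_reflect_fold_change(self, rng):
        d = design_for(10)
        m = self.simulate_matrix(rng, 6, 2, d, fold=3.0)
        # no library-size variation simulated; normalization off so the tiny
        # matrix (where a third of introns carry the effect) is not re-scaled
        records = run_dsa(m, d, DsaConfig(normalize=False))
        by_key = {r.intron_key: r for r in records}
        r = by_key[("chr1", 10, 90, "+")]
        ratio = r.cond_means["disease"] / r.cond_means["control"]
        assert ratio == pytest.approx(3.0, rel=0.35)


def test_testability_filter_requires_positives_per_condition():
    d = design_for(3)
    y = np.array([5, 6, 7, 0, 0, 1])  # disease has one positive sample
    assert not dsa_testability(y, d, min_pos=2)
    assert dsa_testability(np.array([5, 6, 7, 0, 2, 1]), d, min_pos=2)


def test_size_factors_recover_library_scaling(rng):
    base = rng.negative_binomial(10, 10 / (10 + 100), size=(200, 6)).astype(float)
    sf_true = np.array([0.5, 0.8, 1.0, 1.0, 1.25, 2.0])
    counts = np.rint(base * sf_true)
    sf = size_factors(counts)
    ratio = sf / sf_true
    np.testing.assert_allclose(ratio, ratio.mean(), rtol=0.1)
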