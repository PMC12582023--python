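"""Dirichlet-multinomial splicing-ratio model and LRT."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from splicecov.design import SampleSheet, encode
from splicecov.dsr import (
    BunchCounts, DmParams, DsrConfig, bunch_counts_from_matrix, condition_psi,
    dm_loglik, fit_dsr, max_dpsi, run_dsr, softmax_psi,
)
from splicecov.junctions import Bunch, Intron


def design_for(n_per_group=10):
    rows = [
        {"sample_id": f"s{k}_{i}", "condition": cond}
        for k, cond in enumerate(("control", "disease"))
        for i in range(n_per_group)
    ]
    return encode(SampleSheet(pd.DataFrame(rows)), [])


def make_bunch(matrix: np.ndarray, chrom="chr1") -> BunchCounts:
    M = matrix.shape[1]
    introns = [Intron(chrom, 100, 200 + 100 * m, "+") for m in range(M)]
    return BunchCounts(
        bunch=Bunch(id=f"{chrom}:100", introns=introns), matrix=matrix
    )


def dm_sample(rng, n, probs, alpha, size):
    """Draw DM counts: Dirichlet(alpha * p) then multinomial."""
    out = np.zeros((size, len(probs)), dtype=np.int64)
    for i in range(size):
        out[i] = rng.multinomial(n, rng.dirichlet(alpha * np.asarray(probs)))
    return out


class TestSoftmaxPsi:
    def test_uniform_when_all_zero(self):
        p = DmParams(alpha=10.0, intercepts=np.zeros(3), betas=np.zeros((3, 1)))
        np.testing.assert_allclose(softmax_psi(np.zeros(1), p), np.full(3, 1 / 3))

    def test_closed_form_two_introns(self):
        p = DmParams(alpha=10.0, intercepts=np.array([np.log(2.0), 0.0]),
                     betas=np.zeros((2, 1)))
        np.testing.assert_allclose(
            softmax_psi(np.zeros(1), p), [2 / 3, 1 / 3], atol=1e-12
        )

    def test_shift_invariance(self):
        p1 = DmParams(alpha=5.0, intercepts=np.array([1.0, -0.5]),
                      betas=np.array([[0.4], [0.1]]))
        p2 = DmParams(alpha=5.0, intercepts=p1.intercepts + 5.0, betas=p1.betas)
        x = np.array([0.7])
        np.testing.assert_allclose(softmax_psi(x, p1), softmax_psi(x, p2), atol=1e-12)

    def test_sums_to_one(self, rng):
        p = DmParams(alpha=2.0, intercepts=rng.normal(size=4),
                     betas=rng.normal(size=(4, 2)))
        for _ in range(5):
            assert softmax_psi(rng.normal(size=2), p).sum() == pytest.approx(1.0, abs=1e-12)


class TestDmLoglik:
    def test_symmetry_under_column_swap(self):
        d = design_for(1)
        Y = np.array([[5, 5], [7, 7]])
        p = DmParams(alpha=8.0, intercepts=np.array([0.3, 0.3]),
                     betas=np.array([[0.2], [0.2]]))
        b1 = make_bunch(Y)
        b2 = make_bunch(Y[:, ::-1])
        assert dm_loglik(b1, d, p) == pytest.approx(dm_loglik(b2, d, p), abs=1e-10)

    def test_multinomial_limit_large_alpha(self):
        """alpha -> inf: DM collapses onto the multinomial."""
        d = design_for(1)
        Y = np.array([[3, 7, 10], [8, 6, 6]])
        probs = np.array([0.3, 0.3, 0.4])
        p = DmParams(alpha=1e6, intercepts=np.log(probs), betas=np.zeros((3, 1)))
        expected = sum(
            stats.multinomial.logpmf(y, n=y.sum(), p=probs) for y in Y
        )
        assert dm_loglik(make_bunch(Y), d, p) == pytest.approx(expected, abs=1e-4)

    def test_single_draw_large_alpha_is_category_logprob(self):
        rows = [{"sample_id": "s0", "condition": "c1"},
                {"sample_id": "s1", "condition": "c2"}]
        d = encode(SampleSheet(pd.DataFrame(rows)), [])
        p = DmParams(alpha=1e6, intercepts=np.log([0.3, 0.7]), betas=np.zeros((2, 1)))
        ll = dm_loglik(make_bunch(np.array([[1, 0], [0, 0]])), d, p)
        assert ll == pytest.approx(np.log(0.3), abs=1e-4)

    def test_matches_scipy_dirichlet_multinomial(self, rng):
        """Cross-check against scipy's DM pmf with per-sample concentrations."""
        from scipy.stats import dirichlet_multinomial

        d = design_for(2)
        Y = rng.multinomial(40, [0.5, 0.3, 0.2], size=4)
        p = DmParams(alpha=12.0, intercepts=np.array([0.5, -0.2, 0.0]),
                     betas=rng.normal(scale=0.3, size=(3, 1)))
        P = p.probs(d.matrix)
        expected = sum(
            dirichlet_multinomial.logpmf(Y[i], 12.0 * P[i], Y[i].sum())
            for i in range(4)
        )
        assert dm_loglik(make_bunch(Y), d, p) == pytest.approx(expected, abs=1e-8)

    def test_nonfinite_parameters_rejected(self):
        d = design_for(1)
        p = DmParams(alpha=1.0, intercepts=np.array([np.inf, 0.0]),
                     betas=np.zeros((2, 1)))
        with pytest.raises(ValueError, match="non-finite"):
            dm_loglik(make_bunch(np.array([[1, 2], [3, 4]])), d, p)


class TestFit:
    def test_null_psi_recovered(self, rng):
        d = design_for(50)  # N = 100
        Y = dm_sample(rng, 200, [0.7, 0.3], alpha=80, size=100)
        fit = fit_dsr(make_bunch(Y), d, "null")
        assert fit.converged
        # the null fit has no design columns left: PSI is the softmax of the
        # intercepts, shared by every sample
        psi = softmax_psi(np.zeros(0), fit.params)
        assert psi[0] == pytest.approx(0.7, abs=0.05)

    def test_condition_swap_recovered(self, rng):
        d = design_for(50)
        disease = d.samples_in("disease")
        Y = np.vstack([
            dm_sample(rng, 200, [0.3, 0.7] if disease[i] else [0.7, 0.3],
                      alpha=80, size=1)
            for i in range(100)
        ])
        fit = fit_dsr(make_bunch(Y), d, "alternative")
        psi = condition_psi(fit.params, d)
        assert psi["control"][0] == pytest.approx(0.7, abs=0.05)
        assert psi["disease"][0] == pytest.approx(0.3, abs=0.05)

    def test_nesting(self, rng):
        d = design_for(10)
        for _ in range(5):
            Y = dm_sample(rng, 60, [0.5, 0.25, 0.25], alpha=40, size=20)
            f0 = fit_dsr(make_bunch(Y), d, "null")
            f1 = fit_dsr(make_bunch(Y), d, "alternative")
            assert f1.loglik >= f0.loglik - 1e-6

    def test_single_intron_bunch_rejected(self):
        d = design_for(2)
        with pytest.raises(ValueError, match="at least 2"):
            fit_dsr(make_bunch(np.ones((4, 1), dtype=int)), d)

    def test_fitted_probabilities_sum_to_one(self, rng):
        d = design_for(10)
        Y = dm_sample(rng, 80, [0.4, 0.4, 0.2], alpha=30, size=20)
        fit = fit_dsr(make_bunch(Y), d, "alternative")
        P = fit.params.probs(d.matrix)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)


class TestRunDsr:
    def test_power_on_psi_swap(self, rng):
        """A 0.7 -> 0.3 PSI swap at N=20 is called at q <= 0.05."""
        d = design_for(10)
        disease = d.samples_in("disease")
        Y = np.vstack([
            dm_sample(rng, 150, [0.3, 0.7] if disease[i] else [0.7, 0.3],
                      alpha=60, size=1)
            for i in range(20)
        ])
        null_bunches = [
            make_bunch(dm_sample(rng, 150, [0.6, 0.4], alpha=60, size=20),
                       chrom=f"chr{j + 2}")
            for j in range(10)
        ]
        records = run_dsr([make_bunch(Y)] + null_bunches, d)
        rec = next(r for r in records if r.bunch_id == "chr1:100")
        assert rec.q_value <= 0.05
        assert rec.dpsi == pytest.approx(0.4, abs=0.1)

    def test_m1_bunch_skipped(self, rng):
        d = design_for(10)
        single = make_bunch(
            rng.integers(10, 50, size=(20, 1)), chrom="chr9"
        )
        ok = make_bunch(dm_sample(rng, 100, [0.5, 0.5], alpha=50, size=20))
        records = run_dsr([single, ok], d)
        assert [r.bunch_id for r in records] == ["chr1:100"]

    def test_low_coverage_bunch_skipped(self, rng):
        d = design_for(10)
        sparse = make_bunch(np.ones((20, 2), dtype=int))  # totals = 2 < 5
        records = run_dsr([sparse], d, DsrConfig(min_total=5))
        assert records == []

    def test_dpsi_zero_when_no_condition_effect_in_params(self):
        d = design_for(5)
        p = DmParams(alpha=10.0, intercepts=np.array([0.4, 0.0]),
                     betas=np.zeros((2, 1)))  # condition coefficient zero
        assert max_dpsi(condition_psi(p, d)) == 0.0

    def test_raw_psi_rows_sum_to_one(self, rng):
        Y = dm_sample(rng, 50, [0.5, 0.5], alpha=30, size=10)
        psi = make_bunch(Y).raw_psi()
        np.testing.assert_allclose(psi.sum(axis=1), 1.0, atol=1e-9)


def test_bunch_counts_from_matrix_roundtrip(rng):
    from splicecov.junctions import CountMatrix

    Y = rng.integers(0, 30, size=(6, 3))
    introns = [Intron("chr1", 100, 200 + 100 * m, "+") for m in range(3)]
    keys = [iv.key for iv in introns]
    df = pd.DataFrame(Y.T, index=pd.Index(keys, tupleize_cols=False),
                      columns=[f"s{i}" for i in range(6)])
    bc = bunch_counts_from_matrix(
        Bunch(id="b", introns=introns), CountMatrix(df)
    )
    np.testing.assert_array_equal(bc.matrix, Y)
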