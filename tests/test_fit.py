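import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

from genosem import (GeneticCovariance, chisq_diff, fdr_adjust, fit_dwls,
                     fit_indices, parse_model)
from genosem.fit import _fd_jacobian
from genosem.model import RAMModel


def _corr_gc(S, names=None, v=None):
    k = S.shape[0]
    c = k * (k + 1) // 2
    return GeneticCovariance(
        names or [f"t{i}" for i in range(k)], S,
        np.eye(c) if v is None else v, np.zeros((k, k)), "correlation", 0,
    )


def test_triad_loadings_recovered_exactly(triad_gc):
    fit = fit_dwls(triad_gc, parse_model("F =~ a + b + c"), rmsea_n=1000)
    loadings = fit.params.query("op == '=~'")["estimate"].to_numpy()
    assert np.allclose(loadings, [0.8, 0.6, 0.5], atol=1e-6)
    assert fit.df == 0 and fit.chi2 == pytest.approx(0.0, abs=1e-10)
    assert fit.converged
    # derived residual variances complete the unit diagonal
    resid = fit.params.query("op == '~~' and lhs == rhs and lhs != 'F'")
    assert np.allclose(sorted(resid["estimate"]), [0.36, 0.64, 0.75], atol=1e-6)


def test_saturated_model_fits_perfectly(triad_gc):
    spec = parse_model("a ~~ b\na ~~ c\nb ~~ c")
    fit = fit_dwls(triad_gc, spec, rmsea_n=1000)
    assert fit.df == 0
    assert fit.chi2 == pytest.approx(0.0, abs=1e-10)
    assert fit.srmr == pytest.approx(0.0, abs=1e-8)
    assert fit.cfi == 1.0
    assert np.allclose(fit.residuals, 0.0, atol=1e-8)


def test_derivative_free_oracle_agrees():
    """The DWLS optimum must match a derivative-free minimization of the
    same discrepancy (4 indicators, df = 2, non-trivial weights)."""
    S = np.array(
        [[1.0, 0.55, 0.48, 0.42],
         [0.55, 1.0, 0.40, 0.35],
         [0.48, 0.40, 1.0, 0.31],
         [0.42, 0.35, 0.31, 1.0]]
    )
    rng = np.random.default_rng(3)
    d = rng.uniform(0.5, 2.0, size=10)
    gc = _corr_gc(S, names=["a", "b", "c", "d"], v=np.diag(d))
    spec = parse_model("F =~ a + b + c + d")
    fit = fit_dwls(gc, spec, rmsea_n=1000)
    ram = RAMModel(spec, ["a", "b", "c", "d"], profile_variances=True)
    off = [(1, 0), (2, 0), (3, 0), (2, 1), (3, 1), (3, 2)]
    s = np.array([S[i, j] for i, j in off])
    # weights = 1/diag(V) at the off-diagonal slots (slots 1,2,3,5,6,8 of vech)
    w = 1.0 / d[[1, 2, 3, 5, 6, 8]]

    def objective(theta):
        sig = ram.sigma(theta)
        r = s - np.array([sig[i, j] for i, j in off])
        return float(r @ (w * r))

    best = None
    for start in ([0.3] * 4, [0.7] * 4, [0.9, 0.5, 0.5, 0.5]):
        res = optimize.minimize(objective, start, method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-14,
                                         "maxiter": 20000})
        if best is None or res.fun < best.fun:
            best = res
    assert np.allclose(np.abs(fit.theta), np.abs(best.x), atol=1e-5)


def test_fd_jacobian_matches_closed_form_factor_derivatives():
    # for sigma_ij = lambda_i lambda_j (i != j), d sigma_ij / d lambda_a
    # = delta_ai lambda_j + delta_aj lambda_i
    spec = parse_model("F =~ a + b + c\na ~~ 0*a\nb ~~ 0*b\nc ~~ 0*c")
    ram = RAMModel(spec, ["a", "b", "c"], profile_variances=False)
    theta = np.array([0.8, 0.6, 0.5])
    off = [(1, 0), (2, 0), (2, 1)]

    def sig_off(th):
        s = ram.sigma(th)
        return np.array([s[i, j] for i, j in off])

    J = _fd_jacobian(sig_off, theta)
    lam = theta
    expect = np.array(
        [[lam[1], lam[0], 0.0], [lam[2], 0.0, lam[0]], [0.0, lam[2], lam[1]]]
    )
    assert np.allclose(J, expect, atol=1e-8)


def test_ordering_invariance(preset_sim_gc):
    from genosem import impulsivity_model_spec
    spec = impulsivity_model_spec()
    base = fit_dwls(preset_sim_gc, spec, rmsea_n=133_517)
    order = list(range(preset_sim_gc.k))[::-1]
    perm = preset_sim_gc.permute(order)
    other = fit_dwls(perm, spec, rmsea_n=133_517)
    assert other.chi2 == pytest.approx(base.chi2, abs=1e-6)
    assert other.df == base.df
    assert other.cfi == pytest.approx(base.cfi, abs=1e-8)
    assert other.srmr == pytest.approx(base.srmr, abs=1e-8)
    assert other.estimate("premeditation", "~~", "sens_seeking") == pytest.approx(
        base.estimate("premeditation", "~~", "sens_seeking"), abs=1e-6
    )


def test_equality_and_fixing_raise_df_by_one(triad_gc):
    S = np.array(
        [[1.0, 0.5, 0.4, 0.3],
         [0.5, 1.0, 0.35, 0.28],
         [0.4, 0.35, 1.0, 0.22],
         [0.3, 0.28, 0.22, 1.0]]
    )
    gc = _corr_gc(S, names=["a", "b", "c", "d"])
    free = fit_dwls(gc, parse_model("F =~ a + b + c + d"), rmsea_n=100)
    tied = fit_dwls(gc, parse_model("F =~ l1*a + l1*b + c + d"), rmsea_n=100)
    fixed = fit_dwls(gc, parse_model("F =~ 0.7*a + b + c + d"), rmsea_n=100)
    assert tied.df == free.df + 1
    assert fixed.df == free.df + 1


def test_heywood_case_warns():
    S = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, 0.5], [0.9, 0.5, 1.0]])
    gc = _corr_gc(S, names=["a", "b", "c"])
    with pytest.warns(UserWarning, match="Heywood"):
        fit = fit_dwls(gc, parse_model("F =~ a + b + c"), rmsea_n=100)
    assert fit.heywood


# ---------------------------------------------------------------------------
# fit indices


def test_rmsea_zero_at_noncentrality_floor():
    cfi, srmr, rmsea, ci, aic = fit_indices(
        17.0, 17, 100.0, 36, np.zeros((3, 3)), np.eye(3), 5, 10_000
    )
    assert rmsea == 0.0
    assert ci[0] == 0.0


@pytest.mark.parametrize(
    "chi2, df, n, expect",
    [
        (441.49, 17, 133_517, 0.014),
        (2884.55, 78, 133_517, 0.016),
        (135.19, 10, 184_765, 0.008),
    ],
)
def test_rmsea_worked_examples(chi2, df, n, expect):
    _, _, rmsea, _, _ = fit_indices(
        chi2, df, np.nan, 0, np.zeros((2, 2)), np.eye(2), 1, n
    )
    assert round(rmsea, 3) == expect


def test_aic_and_cfi_formulas():
    cfi, srmr, rmsea, ci, aic = fit_indices(
        50.0, 10, 500.0, 45, np.zeros((2, 2)), np.eye(2), 7, 1000
    )
    assert aic == pytest.approx(50.0 + 14.0)
    assert cfi == pytest.approx(((500 - 45) - (50 - 10)) / (500 - 45))
    # worse than the null model clamps to 0
    cfi_bad, *_ = fit_indices(600.0, 10, 500.0, 45, np.zeros((2, 2)),
                              np.eye(2), 7, 1000)
    assert cfi_bad == 0.0


# ---------------------------------------------------------------------------
# difference tests and FDR


def test_identical_fits_give_null_difference(triad_gc):
    spec = parse_model("F =~ a + b + c")
    fit = fit_dwls(triad_gc, spec, rmsea_n=100)
    assert chisq_diff(fit, fit) == (0.0, 0, 1.0)


def test_chi2_difference_p_value():
    class Stub:
        def __init__(self, chi2, df):
            self.chi2, self.df = chi2, df

    dchi, ddf, p = chisq_diff(Stub(13.8415, 9), Stub(10.0, 8))
    assert ddf == 1
    assert round(p, 3) == 0.050
    with pytest.raises(ValueError, match="nesting"):
        chisq_diff(Stub(10.0, 8), Stub(13.8, 9))


def test_fdr_hand_example_and_ties():
    assert np.allclose(fdr_adjust([0.01, 0.02, 0.03, 0.04]),
                       [0.04, 0.04, 0.04, 0.04])
    assert np.allclose(fdr_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
    with pytest.raises(ValueError, match="NaN"):
        fdr_adjust([0.1, np.nan])


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
def test_fdr_dominates_raw_and_respects_rank(p):
    adj = fdr_adjust(np.array(p))
    assert np.all(adj >= np.asarray(p) - 1e-12)
    assert np.all(adj <= 1.0 + 1e-12)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)


def test_chi2_null_calibration_with_known_sampling_covariance():
    """Feeding the fitter the exact sampling covariance of s must yield a
    χ²_df-distributed statistic (Gaussian oracle, k=4 factor, df=2)."""
    lam = np.array([0.8, 0.7, 0.6, 0.5])
    S_true = np.outer(lam, lam)
    np.fill_diagonal(S_true, 1.0)
    k, c = 4, 10
    rng = np.random.default_rng(20)
    A = rng.normal(size=(c, c))
    V = 2e-4 * (A @ A.T + c * np.eye(c))
    L = np.linalg.cholesky(V)
    from genosem.ldsc import unvech, vech
    spec = parse_model("F =~ a + b + c + d")
    s_true = vech(S_true)
    chis = []
    for rep in range(120):
        S = unvech(s_true + L @ rng.standard_normal(c))
        np.fill_diagonal(S, 1.0)
        gc = _corr_gc(S, names=["a", "b", "c", "d"], v=V)
        f = fit_dwls(gc, spec, rmsea_n=1000, compute_null=False)
        chis.append(f.chi2)
    _, p = stats.kstest(chis, lambda x: stats.chi2.cdf(x, 2))
    assert p > 0.01
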