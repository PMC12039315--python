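"""DWLS estimation of SEMs on a genetic covariance matrix with sampling
covariance, plus fit indices, nested-model tests and FDR adjustment.

The estimator minimizes the diagonally weighted least squares discrepancy

    F(θ) = (s - σ(θ))ᵀ D⁻¹ (s - σ(θ)),      D = diag(V),

where s stacks the unique elements of S and V is the block-jackknife
sampling covariance of s.  In correlation metric the diagonal elements of S
are exactly 1 with zero sampling variance, so they are excluded from the
residual vector and free variances are profiled to reproduce the unit
diagonal (see genosem.model).

Because D⁻¹ is not the inverse of the full V, parameter uncertainty uses
the sandwich covariance

    (Δᵀ D⁻¹ Δ)⁻¹ Δᵀ D⁻¹ V D⁻¹ Δ (Δᵀ D⁻¹ Δ)⁻¹,      Δ = ∂σ/∂θ,

and the model χ² is the residual-based statistic

    T = (s - σ̂)ᵀ [V⁺ - V⁺Δ(ΔᵀV⁺Δ)⁻¹ΔᵀV⁺] (s - σ̂),

which is asymptotically χ² on df = (#moments) - (#free θ) even though the
fitting weights are only the diagonal of V.  A pseudo-inverse accommodates
jackknife V of reduced rank.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .ldsc import GeneticCovariance, vech_indices
from .model import ModelSpec, RAMModel, parse_model

__all__ = [
    "FitResult",
    "fit_dwls",
    "fit_indices",
    "chisq_diff",
    "fdr_adjust",
]

_GRAD_TOL = 1e-8
_MAX_ITER = 500
_FD_STEP = 1e-6
_PINV_TOL = 1e-10


# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Estimates, uncertainty, fit statistics and diagnostics for one model."""

    spec: ModelSpec
    params: pd.DataFrame          # lhs, op, rhs, label, free, estimate, se, z,
                                  # p, p_fdr, ci_low, ci_high, std_estimate
    chi2: float
    df: int
    p_chi2: float
    cfi: float
    srmr: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    rmsea_n: int | None
    rmsea_defined: bool
    aic: float
    residuals: np.ndarray         # S - Σ(θ̂) over the model's observed block
    observed: list[str]
    n_free: int                   # free parameters incl. profiled variances
    converged: bool
    n_iter: int
    grad_norm: float
    heywood: bool
    chi2_null: float = np.nan
    df_null: int = 0
    theta: np.ndarray = field(default=None, repr=False)
    theta_cov: np.ndarray = field(default=None, repr=False)
    theta_names: list[str] = field(default_factory=list, repr=False)

    def estimate(self, lhs: str, op: str, rhs: str) -> float:
        """Point estimate of one parameter (order-insensitive for ~~)."""
        t = self.params
        m = (t.lhs == lhs) & (t.op == op) & (t.rhs == rhs)
        if op == "~~" and not m.any():
            m = (t.lhs == rhs) & (t.op == op) & (t.rhs == lhs)
        if not m.any():
            raise KeyError(f"no parameter {lhs} {op} {rhs}")
        return float(t.loc[m, "estimate"].iloc[0])

    def to_json(self, path: str) -> None:
        payload = {
            "observed": self.observed,
            "chi2": self.chi2, "df": self.df, "p_chi2": self.p_chi2,
            "cfi": self.cfi, "srmr": self.srmr,
            "rmsea": self.rmsea, "rmsea_ci": list(self.rmsea_ci),
            "rmsea_n": self.rmsea_n, "rmsea_defined": self.rmsea_defined,
            "aic": self.aic, "n_free": self.n_free,
            "converged": bool(self.converged), "n_iter": self.n_iter,
            "grad_norm": self.grad_norm, "heywood": bool(self.heywood),
            "chi2_null": self.chi2_null, "df_null": self.df_null,
            "parameters": json.loads(self.params.to_json(orient="records")),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# numerical core


def _fd_jacobian(fun, theta: np.ndarray) -> np.ndarray:
    """Central finite differences of a vector map (profiled variances make
    the pure analytic RAM derivative incomplete, so σ is differenced as a
    whole)."""
    f0 = fun(theta)
    J = np.zeros((len(f0), len(theta)))
    for t in range(len(theta)):
        h = _FD_STEP * max(1.0, abs(theta[t]))
        up = theta.copy(); up[t] += h
        dn = theta.copy(); dn[t] -= h
        J[:, t] = (fun(up) - fun(dn)) / (2 * h)
    return J


def _pinv_psd(V: np.ndarray) -> tuple[np.ndarray, int]:
    """Eigenvalue pseudo-inverse of a PSD matrix; returns (V⁺, rank)."""
    w, U = np.linalg.eigh((V + V.T) / 2)
    tol = max(_PINV_TOL, w.max() * len(V) * np.finfo(float).eps) if len(V) else 0.0
    keep = w > tol
    inv = np.where(keep, 1.0 / np.where(keep, w, 1.0), 0.0)
    return (U * inv) @ U.T, int(keep.sum())


def _wishart_correction(n_blocks: int, rank: int) -> float:
    """Finite-resampling correction for quadratic forms in V̂⁺.

    A jackknife V̂ over n_b blocks behaves approximately like a Wishart
    matrix with ν = n_b - 1 degrees of freedom, and E[V̂⁻¹] = ν/(ν-p-1)·V⁻¹
    inflates the residual-based χ² by that factor (the same phenomenon
    Hotelling's T² corrects).  The statistic is therefore rescaled by
    (ν-p-1)/ν when ν > p+1; with few blocks relative to the moment count
    the statistic is unreliable either way and is left unscaled.
    """
    if n_blocks and n_blocks - 1 > rank + 1:
        nu = n_blocks - 1
        return (nu - rank - 1) / nu
    return 1.0


def _gauss_newton(resid_fun, theta0, w):
    """Damped Gauss–Newton (Levenberg) on the weighted residual sum of
    squares; returns (theta, converged, n_iter, grad_norm)."""
    theta = theta0.astype(float).copy()
    if len(theta) == 0:
        return theta, True, 0, 0.0
    lam = 1e-3
    r = resid_fun(theta)
    f = float(r @ (w * r))
    grad_norm = np.inf
    for it in range(1, _MAX_ITER + 1):
        J = _fd_jacobian(resid_fun, theta)
        g = J.T @ (w * r)              # half the gradient of f
        grad_norm = float(np.max(np.abs(2 * g)))
        if grad_norm < _GRAD_TOL * max(1.0, f):
            return theta, True, it, grad_norm
        H = J.T @ (w[:, None] * J)
        dscale = np.clip(np.diag(H), 1e-12, None)
        accepted = False
        for _ in range(40):
            try:
                step = -np.linalg.solve(H + lam * np.diag(dscale), g)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            cand = theta + step
            rc = resid_fun(cand)
            fc = float(rc @ (w * rc))
            if np.isfinite(fc) and fc <= f + 1e-14:
                improvement = f - fc
                theta, r, f = cand, rc, fc
                lam = max(lam * 0.3, 1e-12)
                accepted = True
                if improvement < 1e-15 * max(1.0, f) and np.linalg.norm(step) < 1e-12:
                    return theta, True, it, grad_norm
                break
            lam *= 10
        if not accepted:
            # fall back to scipy's quasi-Newton from the current point
            res = optimize.minimize(
                lambda th: float((lambda rr: rr @ (w * rr))(resid_fun(th))),
                theta, method="Nelder-Mead",
                options={"maxiter": 2000, "xatol": 1e-10, "fatol": 1e-14},
            )
            if res.fun < f:
                theta = res.x
                r = resid_fun(theta)
                f = float(r @ (w * r))
            J = _fd_jacobian(resid_fun, theta)
            g = J.T @ (w * r)
            grad_norm = float(np.max(np.abs(2 * g)))
            return theta, grad_norm < 1e-4 * max(1.0, f), it, grad_norm
    return theta, grad_norm < _GRAD_TOL * max(1.0, f), _MAX_ITER, grad_norm


def _smooth_to_psd(S: np.ndarray, metric: str) -> tuple[np.ndarray, bool]:
    """Eigenvalue-clip a non-PSD S (jackknifed S need not be PSD)."""
    w, U = np.linalg.eigh((S + S.T) / 2)
    if w[0] >= 1e-8:
        return S, False
    w = np.clip(w, 1e-8, None)
    out = (U * w) @ U.T
    if metric == "correlation":
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
        np.fill_diagonal(out, 1.0)
    return out, True


def _sub_vech_positions(k_full: int, trait_pos: list[int]) -> list[int]:
    """vech positions (full ordering) of the subset's unique elements, in
    the subset's own vech ordering."""
    pos = {pair: c for c, pair in enumerate(vech_indices(k_full))}
    out = []
    for i, j in vech_indices(len(trait_pos)):
        a, b = trait_pos[i], trait_pos[j]
        out.append(pos[(max(a, b), min(a, b))])
    return out


# ---------------------------------------------------------------------------


def fit_dwls(
    gc: GeneticCovariance,
    spec: ModelSpec,
    rmsea_n: int | None = None,
    fdr_scope: str = "model",
    compute_null: bool = True,
) -> FitResult:
    """Fit ``spec`` to the (S, V) pair by diagonally weighted least squares.

    ``rmsea_n`` is the sample size entering the RMSEA noncentrality scaling
    (by convention the smallest GWAS among the model's indicators); when
    None, RMSEA is reported as NaN.  ``fdr_scope="model"`` applies
    Benjamini–Hochberg across this model's free parameters; ``"none"``
    leaves p_fdr as NaN (used when a pipeline adjusts jointly across
    models).
    """
    unknown = [v for v in spec.observed if v not in gc.trait_names]
    if unknown:
        raise ValueError(f"model references traits absent from S: {unknown}")
    order = [t for t in gc.trait_names if t in spec.observed]
    trait_pos = [gc.trait_names.index(t) for t in order]
    S_sub = gc.S[np.ix_(trait_pos, trait_pos)]
    sub_pos = _sub_vech_positions(gc.k, trait_pos)
    V_sub = gc.V[np.ix_(sub_pos, sub_pos)]
    S_sub, smoothed = _smooth_to_psd(S_sub, gc.metric)
    if smoothed:
        warnings.warn("S was not positive semidefinite; eigenvalue-clipped")

    correlation = gc.metric == "correlation"
    ram = RAMModel(spec, order, profile_variances=correlation)
    k = len(order)
    sub_idx = vech_indices(k)
    if correlation:
        keep = [c for c, (i, j) in enumerate(sub_idx) if i != j]
    else:
        keep = list(range(len(sub_idx)))
    rows = [sub_idx[c] for c in keep]
    s_red = np.array([S_sub[i, j] for i, j in rows])
    V_red = V_sub[np.ix_(keep, keep)]
    n_slots = len(keep)
    n_theta = ram.n_theta
    df = n_slots - n_theta
    if df < 0:
        raise ValueError(
            f"model is not identified: {n_theta} free parameters exceed "
            f"{n_slots} fitted moments"
        )

    dV = np.clip(np.diag(V_red).copy(), 0.0, None)
    floor = max(dV.max(), 1e-30) * 1e-12
    w = 1.0 / np.maximum(dV, floor)

    def resid(theta):
        sigma = ram.sigma(theta)
        return s_red - np.array([sigma[i, j] for i, j in rows])

    theta0 = ram.start_values(S_sub)
    theta, converged, n_iter, grad_norm = _gauss_newton(resid, theta0, w)

    # --- uncertainty -------------------------------------------------------
    r_hat = resid(theta)
    if n_theta:
        Delta = -_fd_jacobian(resid, theta)      # ∂σ/∂θ
        H = Delta.T @ (w[:, None] * Delta)
        bread = np.linalg.pinv(H)
        meat = Delta.T @ (w[:, None] * V_red * w[None, :]) @ Delta
        theta_cov = bread @ meat @ bread
        theta_se = np.sqrt(np.clip(np.diag(theta_cov), 0.0, None))
    else:
        Delta = np.zeros((n_slots, 0))
        theta_cov = np.zeros((0, 0))
        theta_se = np.zeros(0)

    # --- model chi-square --------------------------------------------------
    if df == 0:
        chi2_val = 0.0
        p_chi2 = np.nan
    else:
        Vp, v_rank = _pinv_psd(V_red)
        if n_theta:
            VpD = Vp @ Delta
            middle = Vp - VpD @ np.linalg.pinv(Delta.T @ VpD) @ VpD.T
        else:
            middle = Vp
        correction = _wishart_correction(gc.n_blocks, v_rank)
        chi2_val = float(max(correction * (r_hat @ middle @ r_hat), 0.0))
        p_chi2 = float(stats.chi2.sf(chi2_val, df))

    # --- independence (null) model for CFI --------------------------------
    if compute_null and df > 0:
        null_text = "\n".join(f"{v} ~~ {v}" for v in order)
        null_spec = parse_model(null_text, identification=spec.identification)
        null_ram = RAMModel(null_spec, order, profile_variances=correlation)

        def null_resid(th):
            sig = null_ram.sigma(th)
            return s_red - np.array([sig[i, j] for i, j in rows])

        th_n, *_ = _gauss_newton(null_resid, null_ram.start_values(S_sub), w)
        rn = null_resid(th_n)
        Vp, v_rank = _pinv_psd(V_red)
        if null_ram.n_theta:
            Dn = -_fd_jacobian(null_resid, th_n)
            VpD = Vp @ Dn
            mid_n = Vp - VpD @ np.linalg.pinv(Dn.T @ VpD) @ VpD.T
        else:
            mid_n = Vp
        correction = _wishart_correction(gc.n_blocks, v_rank)
        chi2_null = float(max(correction * (rn @ mid_n @ rn), 0.0))
        df_null = n_slots - null_ram.n_theta
    else:
        chi2_null, df_null = np.nan, 0

    # --- parameter table ---------------------------------------------------
    sigma_hat, S0, T = ram.sigma_full(theta)
    residuals = S_sub - sigma_hat
    n_free_total = n_theta + ram.n_profiled
    table = _parameter_table(ram, theta, theta_se, S0, T, fdr_scope)
    heywood = bool(
        (table.query("op == '~~' and lhs == rhs")["estimate"] < -1e-10).any()
    )
    if heywood:
        warnings.warn("Heywood case: a residual variance estimate is negative")

    cfi, srmr, rmsea, rmsea_ci, aic = fit_indices(
        chi2_val, df, chi2_null, df_null, residuals, S_sub,
        n_free_total, rmsea_n,
    )

    return FitResult(
        spec=spec, params=table,
        chi2=chi2_val, df=df, p_chi2=p_chi2,
        cfi=cfi, srmr=srmr, rmsea=rmsea, rmsea_ci=rmsea_ci,
        rmsea_n=rmsea_n, rmsea_defined=(df > 0 and rmsea_n is not None),
        aic=aic, residuals=residuals, observed=order,
        n_free=n_free_total, converged=converged, n_iter=n_iter,
        grad_norm=grad_norm, heywood=heywood,
        chi2_null=chi2_null, df_null=df_null,
        theta=theta, theta_cov=theta_cov, theta_names=list(ram.theta_names),
    )


def _parameter_table(ram: RAMModel, theta, theta_se, S0, T, fdr_scope) -> pd.DataFrame:
    spec = ram.spec
    values = np.empty(len(spec.parameters))
    se = np.full(len(spec.parameters), np.nan)
    free_flag = np.zeros(len(spec.parameters), dtype=bool)
    for p_idx, p in enumerate(spec.parameters):
        if not p.free:
            values[p_idx] = p.value
    for t, members in enumerate(ram.theta_classes):
        for m in members:
            values[m] = theta[t]
            se[m] = theta_se[t]
            free_flag[m] = True
    for m in ram.profiled:
        mat, i, j = ram.slots[m]
        values[m] = S0[i, j]
        free_flag[m] = True   # free in the counting sense, profiled numerically
    sd = np.sqrt(np.clip(np.diag(T), 1e-300, None))
    rows = []
    for p_idx, p in enumerate(spec.parameters):
        est = values[p_idx]
        mat, i, j = ram.slots[p_idx]
        if p.op == "=~":
            std = est * sd[ram.vidx[p.lhs]] / sd[ram.vidx[p.rhs]]
        elif p.op == "~":
            std = est * sd[ram.vidx[p.rhs]] / sd[ram.vidx[p.lhs]]
        else:
            da = np.sqrt(max(S0[i, i], 1e-300))
            db = np.sqrt(max(S0[j, j], 1e-300))
            std = est / (da * db) if i != j else est / max(T[i, i], 1e-300)
        s = se[p_idx]
        z = est / s if (np.isfinite(s) and s > 0) else np.nan
        pval = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append({
            "lhs": p.lhs, "op": p.op, "rhs": p.rhs,
            "label": p.label, "free": bool(free_flag[p_idx]),
            "estimate": est, "se": s, "z": z, "p": pval,
            "ci_low": est - 1.959963984540054 * s if np.isfinite(s) else np.nan,
            "ci_high": est + 1.959963984540054 * s if np.isfinite(s) else np.nan,
            "std_estimate": std,
        })
    table = pd.DataFrame(rows)
    table["p_fdr"] = np.nan
    if fdr_scope == "model":
        mask = table["p"].notna().to_numpy()
        if mask.any():
            table.loc[mask, "p_fdr"] = fdr_adjust(table.loc[mask, "p"].to_numpy())
    return table


# ---------------------------------------------------------------------------
# fit indices


def fit_indices(
    chi2_val: float, df: int, chi2_null: float, df_null: int,
    residuals: np.ndarray, S: np.ndarray, n_free: int,
    rmsea_n: int | None,
) -> tuple[float, float, float, tuple[float, float], float]:
    """(CFI, SRMR, RMSEA, RMSEA 90% CI, AIC).

    CFI compares noncentrality against the independence model; SRMR is the
    root mean square of the correlation-metric residuals over all unique
    elements; RMSEA follows sqrt(max(0, (χ²-df) / (df (N-1)))) with a 90%
    CI from inverting the noncentral χ² at 0.05 / 0.95; AIC = χ² + 2·q.
    """
    if df == 0:
        cfi = 1.0
    else:
        denom = chi2_null - df_null
        num = denom - (chi2_val - df)
        cfi = 1.0 if denom <= 0 or not np.isfinite(denom) else float(np.clip(num / denom, 0.0, 1.0))
    d = np.sqrt(np.clip(np.diag(S), 1e-300, None))
    std_res = residuals / np.outer(d, d)
    k = S.shape[0]
    iu = np.triu_indices(k)
    srmr = float(np.sqrt(np.mean(std_res[iu] ** 2)))
    if df == 0 or rmsea_n is None:
        rmsea, ci = (0.0 if df == 0 else np.nan), (np.nan, np.nan)
        if df == 0:
            ci = (0.0, 0.0)
    else:
        scale = df * (rmsea_n - 1)
        rmsea = float(np.sqrt(max(0.0, (chi2_val - df) / scale)))
        ci = (_rmsea_bound(chi2_val, df, rmsea_n, 0.95),
              _rmsea_bound(chi2_val, df, rmsea_n, 0.05))
    aic = float(chi2_val + 2 * n_free)
    return cfi, srmr, rmsea, ci, aic


def _rmsea_bound(chi2_val: float, df: int, n: int, q: float) -> float:
    """λ solving P(χ²_{df,λ} <= chi2) = q, mapped to the RMSEA scale."""
    if stats.chi2.cdf(chi2_val, df) < q:   # λ = 0 already exceeds target
        return 0.0
    hi = max(chi2_val * 2, 10.0)
    while stats.ncx2.cdf(chi2_val, df, hi) > q:
        hi *= 2
        if hi > 1e10:
            break
    lam = optimize.brentq(
        lambda L: stats.ncx2.cdf(chi2_val, df, L) - q, 0.0, hi, xtol=1e-10
    )
    return float(np.sqrt(max(0.0, lam / (df * (n - 1)))))


# ---------------------------------------------------------------------------
# nested tests and multiplicity


def chisq_diff(fit_constrained: FitResult, fit_free: FitResult) -> tuple[float, int, float]:
    """χ² difference test for nested models: (Δχ², Δdf, p)."""
    ddf = fit_constrained.df - fit_free.df
    if ddf < 0:
        raise ValueError(
            "nesting violation: the constrained model has fewer degrees of "
            "freedom than the free model"
        )
    dchi = max(fit_constrained.chi2 - fit_free.chi2, 0.0)
    if ddf == 0:
        return dchi, 0, 1.0
    return dchi, ddf, float(stats.chi2.sf(dchi, ddf))


def fdr_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-values cannot be FDR-adjusted")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
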