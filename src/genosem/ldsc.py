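"""LD score regression: genetic covariance S and sampling covariance V.

Univariate LDSC regresses Z_j^2 on N*ell_j/M with a free intercept; the
slope estimates the SNP heritability and the intercept absorbs confounding.
Cross-trait LDSC regresses Z1_j*Z2_j on sqrt(N1*N2)*ell_j/M; the slope
estimates the genetic covariance and the free intercept absorbs the
sample-overlap term N_s*rho_p/sqrt(N1*N2), which is how downstream models
remain valid when cohorts share participants.

The sampling covariance V of the k(k+1)/2 unique elements of S is obtained
by a block jackknife in which *all* regressions are re-solved under the
same leave-one-block-out deletions, so the sampling dependencies between
elements (driven by shared SNPs and shared samples) are captured, not just
the marginal standard errors.

vech ordering convention (used everywhere downstream): lower triangle,
column-major — (0,0), (1,0), ..., (k-1,0), (1,1), (2,1), ..., (k-1,k-1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .panel import LDScorePanel
from .simulate import SumStatsSet

__all__ = [
    "LDSCOptions",
    "LDSCRegression",
    "GeneticCovariance",
    "ldsc_univariate",
    "ldsc_bivariate",
    "build_S_V",
    "standardize",
    "vech_indices",
    "vech",
    "unvech",
]

_EIG_TOL = 1e-10


# ---------------------------------------------------------------------------
# vech helpers (lower triangle, column-major)


def vech_indices(k: int) -> list[tuple[int, int]]:
    """(row, col) pairs of the lower triangle in column-major order."""
    return [(i, j) for j in range(k) for i in range(j, k)]


def vech(mat: np.ndarray) -> np.ndarray:
    k = mat.shape[0]
    return np.array([mat[i, j] for i, j in vech_indices(k)])


def unvech(v: np.ndarray) -> np.ndarray:
    c = len(v)
    k = int((np.sqrt(8 * c + 1) - 1) / 2)
    out = np.zeros((k, k))
    for val, (i, j) in zip(v, vech_indices(k)):
        out[i, j] = out[j, i] = val
    return out


# ---------------------------------------------------------------------------


@dataclass
class LDSCOptions:
    """Tuning knobs for the LDSC regressions.

    weights: "two-step" (default) uses a first unweighted pass to estimate
        each trait's heritability h2_0, then weights SNP j by
        1 / (ell_j * (1 + N_i h2_0i ell_j / M)(1 + N_m h2_0m ell_j / M)),
        the standard heteroskedasticity correction; "unit" disables
        weighting (used by closed-form oracle tests).
    max_chisq: SNPs with Z^2 > max(max_chisq, chisq_n_frac * N) are dropped
        before regression (outlier robustness, as in standard munging);
        set to None to disable.
    """

    weights: str = "two-step"
    max_chisq: float | None = 80.0
    chisq_n_frac: float = 0.001

    def chisq_cut(self, N: float) -> float | None:
        if self.max_chisq is None:
            return None
        return max(self.max_chisq, self.chisq_n_frac * N)


@dataclass
class LDSCRegression:
    """One LDSC regression: full-sample fit plus delete-one-block fits."""

    slope: float
    intercept: float
    slope_delete: np.ndarray      # n_blocks delete-one slope estimates
    intercept_delete: np.ndarray
    n_snps_used: int

    @property
    def n_blocks(self) -> int:
        return len(self.slope_delete)

    def _jk_se(self, delete: np.ndarray) -> float:
        nb = len(delete)
        return float(np.sqrt((nb - 1) / nb * np.sum((delete - delete.mean()) ** 2)))

    @property
    def slope_se(self) -> float:
        return self._jk_se(self.slope_delete)

    @property
    def intercept_se(self) -> float:
        return self._jk_se(self.intercept_delete)


def _wls_jackknife(x, y, w, block_id, n_blocks) -> LDSCRegression:
    """Weighted 2-parameter regression with leave-one-block-out re-solves.

    Uses per-block sufficient statistics so each deletion is a subtraction,
    which is algebraically identical to refitting from scratch.
    """
    if np.ptp(x) < 1e-12:
        raise ValueError("LD scores are constant: the slope is unidentified")
    stats = np.stack([w, w * x, w * y, w * x * x, w * x * y], axis=1)
    totals = stats.sum(axis=0)
    per_block = np.zeros((n_blocks, 5))
    np.add.at(per_block, block_id, stats)

    def solve(s):
        sw, swx, swy, swxx, swxy = s
        det = sw * swxx - swx * swx
        if abs(det) < 1e-30:
            raise ValueError("degenerate regression after block deletion")
        slope = (sw * swxy - swx * swy) / det
        intercept = (swxx * swy - swx * swxy) / det
        return slope, intercept

    slope, intercept = solve(totals)
    dd = totals[None, :] - per_block
    sw, swx, swy, swxx, swxy = dd.T
    det = sw * swxx - swx * swx
    if np.any(np.abs(det) < 1e-30):
        raise ValueError("degenerate regression after block deletion")
    sd = (sw * swxy - swx * swy) / det
    id_ = (swxx * swy - swx * swxy) / det
    return LDSCRegression(slope, intercept, sd, id_, len(x))


def _weights(panel, N1, N2, h2a, h2b, opts: LDSCOptions) -> np.ndarray:
    if opts.weights == "unit":
        return np.ones(panel.n_snps)
    if opts.weights != "two-step":
        raise ValueError(f"unknown weight scheme {opts.weights!r}")
    ell = panel.ld_score
    f1 = 1.0 + N1 * h2a * ell / panel.M
    f2 = 1.0 + N2 * h2b * ell / panel.M
    return 1.0 / (ell * f1 * f2)


def _pair_regression(z1, z2, N1, N2, panel, h2a, h2b, opts) -> LDSCRegression:
    x = np.sqrt(float(N1) * float(N2)) * panel.ld_score / panel.M
    y = z1 * z2
    mask = np.ones(panel.n_snps, dtype=bool)
    cut1, cut2 = opts.chisq_cut(N1), opts.chisq_cut(N2)
    if cut1 is not None:
        mask &= z1 * z1 <= cut1
    if cut2 is not None:
        mask &= z2 * z2 <= cut2
    if mask.sum() < 2 * panel.n_blocks:
        raise ValueError(
            f"only {int(mask.sum())} SNPs available for regression; need at "
            f"least twice the number of jackknife blocks ({panel.n_blocks})"
        )
    w = _weights(panel, N1, N2, h2a, h2b, opts)
    return _wls_jackknife(x[mask], y[mask], w[mask], panel.block_id[mask],
                          panel.n_blocks)


def _pass1_h2(z, N, panel, opts) -> float:
    """First-pass heritability (unit weights, same outlier filter)."""
    pass_opts = LDSCOptions(weights="unit", max_chisq=opts.max_chisq,
                            chisq_n_frac=opts.chisq_n_frac)
    reg = _pair_regression(z, z, N, N, panel, 0.0, 0.0, pass_opts)
    return float(np.clip(reg.slope, 0.0, 1.0))


def ldsc_univariate(
    z: np.ndarray, N: int, panel: LDScorePanel, opts: LDSCOptions | None = None
) -> LDSCRegression:
    """Estimate SNP heritability (slope) and intercept for one trait."""
    opts = opts or LDSCOptions()
    if N <= 1:
        raise ValueError("sample size must exceed 1")
    h2_0 = _pass1_h2(z, N, panel, opts) if opts.weights == "two-step" else 0.0
    return _pair_regression(z, z, N, N, panel, h2_0, h2_0, opts)


def ldsc_bivariate(
    z1, z2, N1, N2, panel: LDScorePanel, opts: LDSCOptions | None = None
) -> LDSCRegression:
    """Estimate genetic covariance (slope) and cross-trait intercept."""
    opts = opts or LDSCOptions()
    if opts.weights == "two-step":
        h2a = _pass1_h2(z1, N1, panel, opts)
        h2b = _pass1_h2(z2, N2, panel, opts)
    else:
        h2a = h2b = 0.0
    return _pair_regression(z1, z2, N1, N2, panel, h2a, h2b, opts)


# ---------------------------------------------------------------------------


@dataclass
class GeneticCovariance:
    """LDSC output: S, its sampling covariance V, and the intercept matrix.

    S is k × k (covariance or correlation per ``metric``); V is c × c with
    c = k(k+1)/2, the block-jackknife covariance of vech(S) in the fixed
    lower-triangle column-major ordering of :func:`vech_indices`.  The
    intercept matrix holds univariate intercepts on the diagonal and
    cross-trait intercepts off it; intercepts are *not* folded into S.
    """

    trait_names: list[str]
    S: np.ndarray
    V: np.ndarray
    intercepts: np.ndarray
    metric: str = "covariance"
    n_blocks: int = 0

    def __post_init__(self) -> None:
        k = len(self.trait_names)
        c = k * (k + 1) // 2
        self.S = np.asarray(self.S, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.S.shape != (k, k):
            raise ValueError("S has wrong shape")
        if self.V.shape != (c, c):
            raise ValueError(f"V must be {c}x{c} for k={k}")
        if not np.allclose(self.S, self.S.T, atol=1e-8):
            raise ValueError("S must be symmetric")
        if self.metric not in ("covariance", "correlation"):
            raise ValueError("metric must be 'covariance' or 'correlation'")

    @property
    def k(self) -> int:
        return len(self.trait_names)

    def permute(self, order: list[int]) -> "GeneticCovariance":
        """Reorder traits; S and V's vech indexing are permuted consistently."""
        k = self.k
        idx = vech_indices(k)
        pos = {pair: c for c, pair in enumerate(idx)}
        new_to_old = []
        for i, j in idx:
            a, b = order[i], order[j]
            new_to_old.append(pos[(max(a, b), min(a, b))])
        P = np.array(new_to_old)
        return GeneticCovariance(
            [self.trait_names[o] for o in order],
            self.S[np.ix_(order, order)],
            self.V[np.ix_(P, P)],
            self.intercepts[np.ix_(order, order)],
            self.metric,
            self.n_blocks,
        )

    def to_json(self, path: str) -> None:
        payload = {
            "trait_names": self.trait_names,
            "metric": self.metric,
            "n_blocks": self.n_blocks,
            "vech_ordering": "lower-triangle column-major",
            "S": self.S.tolist(),
            "V": self.V.tolist(),
            "intercepts": self.intercepts.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "GeneticCovariance":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            payload["trait_names"],
            np.asarray(payload["S"]),
            np.asarray(payload["V"]),
            np.asarray(payload["intercepts"]),
            payload.get("metric", "covariance"),
            payload.get("n_blocks", 0),
        )


def build_S_V(
    ss: SumStatsSet, panel: LDScorePanel | None = None,
    opts: LDSCOptions | None = None,
) -> GeneticCovariance:
    """Assemble S (covariance metric) and its joint block-jackknife V.

    All c = k(k+1)/2 regressions are solved under the same
    leave-one-block-out deletions and the c-vector of delete-one slopes is
    covaried across blocks:  V = ((n_b-1)/n_b) * sum_b (θ_(b)-θ̄)(θ_(b)-θ̄)ᵀ.
    """
    panel = panel or ss.panel
    opts = opts or LDSCOptions()
    k = ss.n_traits
    if k < 2:
        raise ValueError("need at least two traits")
    nb = panel.n_blocks
    h2_0 = np.zeros(k)
    if opts.weights == "two-step":
        for t in range(k):
            h2_0[t] = _pass1_h2(ss.Z[:, t], ss.N[t], panel, opts)
    idx = vech_indices(k)
    c = len(idx)
    S = np.zeros((k, k))
    intercepts = np.zeros((k, k))
    delete = np.zeros((nb, c))
    for col, (i, j) in enumerate(idx):
        try:
            reg = _pair_regression(
                ss.Z[:, i], ss.Z[:, j], ss.N[i], ss.N[j], panel,
                h2_0[i], h2_0[j], opts,
            )
        except ValueError as err:
            raise ValueError(
                f"LDSC regression failed for trait pair "
                f"({ss.trait_names[i]!r}, {ss.trait_names[j]!r}): {err}"
            ) from err
        S[i, j] = S[j, i] = reg.slope
        intercepts[i, j] = intercepts[j, i] = reg.intercept
        delete[:, col] = reg.slope_delete
    centered = delete - delete.mean(axis=0)
    V = (nb - 1) / nb * centered.T @ centered
    return GeneticCovariance(list(ss.trait_names), S, V, intercepts,
                             "covariance", nb)


def standardize(gc: GeneticCovariance) -> GeneticCovariance:
    """Convert to correlation metric with a delta-method transform of V.

    S'_{im} = S_{im}/sqrt(S_{ii} S_{mm}); V' = J V Jᵀ with J the exact
    Jacobian of that map.  Diagonal elements of S' are exactly 1 with zero
    sampling variance (their V' rows/columns are zero).
    """
    if gc.metric == "correlation":
        return gc
    d = np.diag(gc.S)
    if np.any(d <= 0):
        bad = [gc.trait_names[t] for t in np.where(d <= 0)[0]]
        raise ValueError(
            f"nonpositive heritability estimate for {bad}; cannot standardize"
        )
    k = gc.k
    idx = vech_indices(k)
    pos = {pair: c for c, pair in enumerate(idx)}
    rootd = np.sqrt(d)
    Snew = gc.S / np.outer(rootd, rootd)
    np.fill_diagonal(Snew, 1.0)
    c = len(idx)
    J = np.zeros((c, c))
    for row, (i, j) in enumerate(idx):
        if i == j:
            continue  # maps to the constant 1
        r = Snew[i, j]
        J[row, pos[(i, j)]] = 1.0 / (rootd[i] * rootd[j])
        J[row, pos[(i, i)]] = -0.5 * r / d[i]
        J[row, pos[(j, j)]] = -0.5 * r / d[j]
    Vnew = J @ gc.V @ J.T
    return GeneticCovariance(list(gc.trait_names), Snew, Vnew,
                             gc.intercepts.copy(), "correlation", gc.n_blocks)
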