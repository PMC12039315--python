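"""Generative latent genetic factor architectures for simulation.

A :class:`FactorArchitecture` is the ground truth behind a simulated set of
GWAS: a loading matrix Λ (traits × factors, genetic-standardized units), a
factor covariance Ψ with unit diagonal, a residual genetic covariance Θ,
per-trait SNP heritabilities h², GWAS sample sizes N, pairwise overlapping
sample counts N_s and phenotypic correlations ρ_p.  The implied true
genetic correlation matrix is R_g = ΛΨΛᵀ + Θ, which must have unit diagonal
and be positive semidefinite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "FactorArchitecture",
    "implied_genetic_correlation",
    "load_architecture",
    "save_architecture",
]

_PSD_TOL = 1e-8


@dataclass
class FactorArchitecture:
    """Ground truth for a k-trait, q-factor genetic architecture."""

    trait_names: list[str]
    loadings: np.ndarray          # Λ, k × q
    factor_cov: np.ndarray        # Ψ, q × q, unit diagonal
    residual_cov: np.ndarray      # Θ, k × k (diagonal unless stated)
    h2: np.ndarray                # per-trait SNP heritability, in [0, 1]
    N: np.ndarray                 # per-trait GWAS sample size
    N_overlap: np.ndarray = None  # N_s, k × k, diag = N
    pheno_corr: np.ndarray = None  # ρ_p, k × k, diag = 1
    factor_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        k = len(self.trait_names)
        self.loadings = np.atleast_2d(np.asarray(self.loadings, dtype=float))
        self.factor_cov = np.atleast_2d(np.asarray(self.factor_cov, dtype=float))
        self.residual_cov = np.atleast_2d(np.asarray(self.residual_cov, dtype=float))
        self.h2 = np.asarray(self.h2, dtype=float)
        self.N = np.asarray(self.N, dtype=int)
        if self.N_overlap is None:
            self.N_overlap = np.diag(self.N).astype(float)
        self.N_overlap = np.asarray(self.N_overlap, dtype=float)
        if self.pheno_corr is None:
            self.pheno_corr = np.eye(k)
        self.pheno_corr = np.asarray(self.pheno_corr, dtype=float)
        if not self.factor_names:
            self.factor_names = [f"F{i + 1}" for i in range(self.loadings.shape[1])]
        self._validate()

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    def _validate(self) -> None:
        k, q = self.n_traits, self.n_factors
        if self.loadings.shape != (k, q):
            raise ValueError(f"loadings must be {k}x{q}, got {self.loadings.shape}")
        if self.factor_cov.shape != (q, q):
            raise ValueError("factor covariance has wrong shape")
        if not np.allclose(np.diag(self.factor_cov), 1.0, atol=1e-10):
            raise ValueError("factor covariance must have unit diagonal")
        if self.residual_cov.shape != (k, k):
            raise ValueError("residual covariance has wrong shape")
        if np.any(self.h2 < 0) or np.any(self.h2 > 1):
            raise ValueError("heritabilities must lie in [0, 1]")
        if np.any(self.N <= 0):
            raise ValueError("sample sizes must be positive")
        if not np.allclose(self.N_overlap, self.N_overlap.T):
            raise ValueError("overlap matrix must be symmetric")
        if not np.allclose(np.diag(self.N_overlap), self.N):
            raise ValueError("overlap diagonal must equal the sample sizes")
        nmin = np.minimum.outer(self.N, self.N)
        if np.any(self.N_overlap > nmin + 1e-9):
            raise ValueError("overlap N_s[i,j] cannot exceed min(N_i, N_j)")
        if np.any(np.abs(self.pheno_corr) > 1 + 1e-12):
            raise ValueError("phenotypic correlations must lie in [-1, 1]")
        if not np.allclose(self.pheno_corr, self.pheno_corr.T):
            raise ValueError("phenotypic correlation matrix must be symmetric")
        implied_genetic_correlation(self)  # raises on bad diagonal / non-PSD


def implied_genetic_correlation(arch: FactorArchitecture) -> np.ndarray:
    """True genetic correlation matrix R_g = ΛΨΛᵀ + Θ.

    Raises if the result does not have a unit diagonal or is not positive
    semidefinite (the offending smallest eigenvalue is reported).
    """
    R = arch.loadings @ arch.factor_cov @ arch.loadings.T + arch.residual_cov
    R = (R + R.T) / 2.0
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        bad = int(np.argmax(np.abs(np.diag(R) - 1.0)))
        raise ValueError(
            f"implied genetic correlation diagonal is not 1 for trait "
            f"{arch.trait_names[bad]!r} (got {R[bad, bad]:.6f})"
        )
    w = np.linalg.eigvalsh(R)
    if w[0] < -_PSD_TOL:
        raise ValueError(
            f"implied genetic correlation matrix is not positive semidefinite "
            f"(smallest eigenvalue {w[0]:.3e})"
        )
    return R


# ---------------------------------------------------------------------------
# YAML round-trip


def save_architecture(arch: FactorArchitecture, path: str) -> None:
    payload = {
        "trait_names": list(arch.trait_names),
        "factor_names": list(arch.factor_names),
        "loadings": arch.loadings.tolist(),
        "factor_cov": arch.factor_cov.tolist(),
        "residual_cov": arch.residual_cov.tolist(),
        "h2": arch.h2.tolist(),
        "N": arch.N.tolist(),
        "N_overlap": arch.N_overlap.tolist(),
        "pheno_corr": arch.pheno_corr.tolist(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_architecture(path: str) -> FactorArchitecture:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    required = {"trait_names", "loadings", "factor_cov", "residual_cov", "h2", "N"}
    missing = required - payload.keys()
    if missing:
        raise ValueError(f"architecture file is missing keys: {sorted(missing)}")
    return FactorArchitecture(
        trait_names=list(payload["trait_names"]),
        loadings=np.asarray(payload["loadings"], dtype=float),
        factor_cov=np.asarray(payload["factor_cov"], dtype=float),
        residual_cov=np.asarray(payload["residual_cov"], dtype=float),
        h2=np.asarray(payload["h2"], dtype=float),
        N=np.asarray(payload["N"], dtype=int),
        N_overlap=(
            np.asarray(payload["N_overlap"], dtype=float)
            if "N_overlap" in payload else None
        ),
        pheno_corr=(
            np.asarray(payload["pheno_corr"], dtype=float)
            if "pheno_corr" in payload else None
        ),
        factor_names=list(payload.get("factor_names", [])),
    )
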