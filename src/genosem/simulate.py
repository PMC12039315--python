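"""Simulation of multivariate GWAS Z-statistics under the LDSC moment model.

For SNP j with LD score ell_j the k-vector of trait Z-statistics is drawn
independently across SNPs from a multivariate normal with covariance

    C_j = (ell_j / M) * G + E,

    G[i,m] = sqrt(N_i N_m) * cov_g(i, m),        cov_g = R_g * sqrt(h2_i h2_m)
    E[i,m] = N_s[i,m] * rho_p[i,m] / sqrt(N_i N_m),   E[i,i] = 1.

The genetic term G carries the polygenic signal (an infinitesimal,
Gaussian-effects architecture); E is the correlation of the per-study
sampling noise, nonzero off the diagonal exactly when cohorts share
participants.  These are the second moments LD score regression fits, so
the simulator is the weakest generator under which the downstream LDSC
stage is consistent.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .architecture import FactorArchitecture, implied_genetic_correlation
from .panel import LDScorePanel

__all__ = ["SumStatsSet", "simulate_zscores", "write_sumstats", "read_sumstats"]

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PSD_JITTER = 1e-10  # added to the diagonal of G and E if eigmin dips below 0


@dataclass
class SumStatsSet:
    """Aligned per-trait GWAS summary statistics sharing one SNP ordering."""

    panel: LDScorePanel
    trait_names: list[str]
    Z: np.ndarray                # M_panel × k
    N: np.ndarray                # per-trait sample size (constant per SNP)
    a1: np.ndarray
    a2: np.ndarray

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.shape != (self.panel.n_snps, len(self.trait_names)):
            raise ValueError("Z must be (n_snps, n_traits) aligned to the panel")
        if not np.all(np.isfinite(self.Z)):
            raise ValueError("Z statistics must be finite")

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)


def _psd_sqrt(mat: np.ndarray, name: str) -> np.ndarray:
    """Symmetric PSD square root; tolerates rank deficiency, rejects indefinite."""
    sym = (mat + mat.T) / 2.0
    w, U = np.linalg.eigh(sym)
    if w[0] < -1e-8 * max(1.0, w[-1]):
        sym = sym + _PSD_JITTER * np.eye(len(sym))
        w, U = np.linalg.eigh(sym)
        if w[0] < -1e-8 * max(1.0, w[-1]):
            raise ValueError(
                f"{name} component of the Z covariance is not positive "
                f"semidefinite (smallest eigenvalue {w[0]:.3e})"
            )
    return U @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ U.T


def simulate_zscores(
    panel: LDScorePanel, arch: FactorArchitecture, seed: int
) -> SumStatsSet:
    """Draw per-SNP Z-vectors from the LDSC moment model; seed-deterministic.

    Exploits C_j = (ell_j/M) G + E: Z_j = sqrt(ell_j/M) * G^{1/2} u_j
    + E^{1/2} v_j with independent standard-normal u, v, which is exact and
    vectorizes over SNPs.
    """
    Rg = implied_genetic_correlation(arch)
    rootN = np.sqrt(arch.N.astype(float))
    covg = Rg * np.sqrt(np.outer(arch.h2, arch.h2))
    G = np.outer(rootN, rootN) * covg
    E = arch.N_overlap * arch.pheno_corr / np.outer(rootN, rootN)
    np.fill_diagonal(E, 1.0)
    Lg = _psd_sqrt(G, "genetic")
    Le = _psd_sqrt(E, "sampling")
    rng = np.random.default_rng(seed)
    m, k = panel.n_snps, arch.n_traits
    U = rng.standard_normal((m, k))
    V = rng.standard_normal((m, k))
    scale = np.sqrt(panel.ld_score / panel.M)[:, None]
    Z = scale * (U @ Lg.T) + V @ Le.T
    if panel.a1 is None:
        raise ValueError("panel carries no reference alleles; simulate from make_ld_panel")
    return SumStatsSet(panel, list(arch.trait_names), Z, arch.N.copy(),
                       panel.a1.copy(), panel.a2.copy())


# ---------------------------------------------------------------------------
# munged-sumstats file IO (SNP A1 A2 N Z)


def write_sumstats(ss: SumStatsSet, directory: str | os.PathLike) -> list[str]:
    """One whitespace-delimited file per trait, header ``SNP A1 A2 N Z``."""
    os.makedirs(directory, exist_ok=True)
    paths = []
    for t, name in enumerate(ss.trait_names):
        df = pd.DataFrame(
            {
                "SNP": ss.panel.snp_id,
                "A1": ss.a1,
                "A2": ss.a2,
                "N": np.full(ss.panel.n_snps, ss.N[t], dtype=int),
                "Z": ss.Z[:, t],
            }
        )
        path = os.path.join(directory, f"{name}.sumstats")
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
        paths.append(path)
    return paths


def _read_one(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", float_precision="round_trip")
    for col in ("SNP", "A1", "A2", "N", "Z"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if not np.issubdtype(pd.to_numeric(df["Z"], errors="coerce").dtype, np.number) or (
        pd.to_numeric(df["Z"], errors="coerce").isna() & df["Z"].notna()
    ).any():
        raise ValueError(f"{path}: non-numeric Z values")
    df["Z"] = pd.to_numeric(df["Z"])
    df["A1"] = df["A1"].str.upper()
    df["A2"] = df["A2"].str.upper()
    return df


def read_sumstats(
    paths: list[str],
    panel: LDScorePanel,
    trait_names: list[str] | None = None,
    drop_ambiguous: bool = True,
) -> SumStatsSet:
    """Read and align per-trait sumstats files against the panel.

    Alignment follows standard munging practice: SNPs absent from the panel
    are dropped; strand-ambiguous SNPs (A/T, C/G) are dropped (configurable);
    Z is negated when A1/A2 are swapped relative to the reference alleles
    (directly or on the complementary strand); SNPs whose alleles cannot be
    reconciled are dropped.  When the panel carries no reference alleles the
    first file read defines them.  Only SNPs observed with consistent
    alleles in every trait are retained; the returned set (and a copy of the
    panel restricted to surviving SNPs) share one SNP ordering.
    """
    if trait_names is None:
        trait_names = [os.path.splitext(os.path.basename(p))[0] for p in paths]
    ref_a1, ref_a2 = panel.a1, panel.a2
    m = panel.n_snps
    keep = np.ones(m, dtype=bool)
    Z = np.zeros((m, len(paths)))
    N = np.zeros(len(paths), dtype=int)
    for t, path in enumerate(paths):
        df = _read_one(path)
        idx = panel.locate(df["SNP"].to_numpy(dtype=object))
        present = idx >= 0
        df, idx = df[present], idx[present]
        a1 = df["A1"].to_numpy(dtype=object)
        a2 = df["A2"].to_numpy(dtype=object)
        if drop_ambiguous:
            ambig = np.array([(x, y) in _AMBIGUOUS for x, y in zip(a1, a2)])
            df, idx, a1, a2 = df[~ambig], idx[~ambig], a1[~ambig], a2[~ambig]
        if ref_a1 is None:
            ref_a1 = np.full(m, None, dtype=object)
            ref_a2 = np.full(m, None, dtype=object)
            ref_a1[idx], ref_a2[idx] = a1, a2
        comp1 = np.array([_COMPLEMENT.get(x, "?") for x in a1], dtype=object)
        comp2 = np.array([_COMPLEMENT.get(x, "?") for x in a2], dtype=object)
        r1, r2 = ref_a1[idx], ref_a2[idx]
        same = ((a1 == r1) & (a2 == r2)) | ((comp1 == r1) & (comp2 == r2))
        flipped = ((a1 == r2) & (a2 == r1)) | ((comp1 == r2) & (comp2 == r1))
        ok = same | flipped
        df, idx = df[ok], idx[ok]
        sign = np.where(flipped[ok], -1.0, 1.0)
        seen = np.zeros(m, dtype=bool)
        seen[idx] = True
        keep &= seen
        Z[idx, t] = sign * df["Z"].to_numpy(dtype=float)
        n_vals = df["N"].to_numpy()
        N[t] = int(np.round(np.median(n_vals))) if len(n_vals) else 0
    sub = _subset_panel(panel, keep, ref_a1, ref_a2)
    return SumStatsSet(sub, trait_names, Z[keep], N, ref_a1[keep], ref_a2[keep])


def _subset_panel(panel, mask, ref_a1, ref_a2) -> LDScorePanel:
    block = panel.block_id[mask]
    # re-pack block ids so that every original block that survives stays
    # nonempty and contiguity is preserved
    uniq = np.unique(block)
    remap = {b: i for i, b in enumerate(uniq)}
    block = np.array([remap[b] for b in block], dtype=int)
    return LDScorePanel(
        panel.snp_id[mask], panel.chrom[mask], panel.bp[mask],
        panel.ld_score[mask], panel.M, block,
        ref_a1[mask] if ref_a1 is not None else None,
        ref_a2[mask] if ref_a2 is not None else None,
    )
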