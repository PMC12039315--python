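"""Reference panel of LD scores used by LD score regression.

LD score regression (LDSC) consumes, for each SNP j, its LD score ell_j —
the sum of squared correlations between j and nearby variants in a reference
panel — together with M, the number of SNPs over which the SNP heritability
is spread.  The panel also carries a contiguous block assignment used for
block-jackknife resampling of the regression estimates.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LDScorePanel", "make_ld_panel", "read_ld_panel", "write_ld_panel"]

#: shape of the Gamma distribution used for the LD-score excess (ell - 1).
#: Mean is set by ``ld_mean``; shape 2 gives a right-skewed but not extreme
#: distribution, qualitatively like genome-wide LD-score histograms.
_GAMMA_SHAPE = 2.0

# unambiguous biallelic pairs used for simulated reference alleles
_ALLELE_PAIRS = np.array([("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")])


@dataclass
class LDScorePanel:
    """Per-SNP LD scores, reference SNP count M and jackknife blocks.

    Attributes
    ----------
    snp_id : ndarray of str, unique identifiers, length M_panel.
    chrom, bp : ndarray of int, nominal genomic coordinates (position order).
    ld_score : ndarray of float, ell_j >= 1 (a SNP is in LD with itself).
    M : int, number of SNPs heritability is spread over.
    block_id : ndarray of int in [0, n_blocks), contiguous in position order.
    a1, a2 : optional reference alleles used for strand/sign alignment of
        summary statistics; None when the panel was loaded from a plain
        LD-score file, in which case the first aligned trait defines them.
    """

    snp_id: np.ndarray
    chrom: np.ndarray
    bp: np.ndarray
    ld_score: np.ndarray
    M: int
    block_id: np.ndarray
    a1: np.ndarray | None = None
    a2: np.ndarray | None = None
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.ld_score = np.asarray(self.ld_score, dtype=float)
        self.block_id = np.asarray(self.block_id, dtype=int)
        if len(set(self.snp_id)) != self.snp_id.size:
            raise ValueError("panel SNP identifiers must be unique")
        if np.any(self.ld_score < 1.0 - 1e-12):
            raise ValueError("LD scores must be >= 1 (a SNP is in LD with itself)")
        counts = np.bincount(self.block_id, minlength=self.n_blocks)
        if np.any(counts == 0):
            raise ValueError("every jackknife block must be nonempty")
        self._index = {s: i for i, s in enumerate(self.snp_id)}

    @property
    def n_snps(self) -> int:
        return int(self.snp_id.size)

    @property
    def n_blocks(self) -> int:
        return int(self.block_id.max()) + 1

    def locate(self, snp_ids) -> np.ndarray:
        """Row index of each identifier; -1 where absent from the panel."""
        return np.array([self._index.get(s, -1) for s in snp_ids], dtype=int)


def make_ld_panel(M_panel: int, n_blocks: int, ld_mean: float, seed: int) -> LDScorePanel:
    """Simulate an LD-score panel of ``M_panel`` SNPs.

    LD scores are drawn i.i.d. as ``1 + Gamma`` with mean ``ld_mean - 1``
    (shape 2); ``ld_mean == 1`` is the degenerate limit where every score is
    exactly 1.  Blocks are contiguous in position order and near-equal in
    size.  M is set to the panel size.  Deterministic given ``seed``.
    """
    if M_panel < n_blocks:
        raise ValueError(
            f"cannot jackknife: M_panel={M_panel} < n_blocks={n_blocks}"
        )
    if n_blocks < 2:
        raise ValueError("need at least 2 jackknife blocks")
    if ld_mean < 1.0:
        raise ValueError("ld_mean must be >= 1")
    rng = np.random.default_rng(seed)
    excess_mean = ld_mean - 1.0
    if excess_mean > 0:
        ell = 1.0 + rng.gamma(_GAMMA_SHAPE, excess_mean / _GAMMA_SHAPE, size=M_panel)
    else:
        ell = np.ones(M_panel)
    snp_id = np.array([f"rs{j + 1}" for j in range(M_panel)], dtype=object)
    chrom = np.ones(M_panel, dtype=int)
    bp = np.arange(1, M_panel + 1, dtype=int) * 1000
    block_id = np.concatenate(
        [np.full(len(part), b) for b, part in enumerate(np.array_split(np.arange(M_panel), n_blocks))]
    )
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=M_panel)
    a1 = _ALLELE_PAIRS[pair_idx, 0].astype(object)
    a2 = _ALLELE_PAIRS[pair_idx, 1].astype(object)
    return LDScorePanel(snp_id, chrom, bp, ell, int(M_panel), block_id, a1, a2)


def write_ld_panel(panel: LDScorePanel, directory: str | os.PathLike) -> None:
    """Write ``ldscores.l2.ldscore`` (CHR SNP BP L2) and ``ldscores.l2.M``."""
    os.makedirs(directory, exist_ok=True)
    df = pd.DataFrame(
        {"CHR": panel.chrom, "SNP": panel.snp_id, "BP": panel.bp, "L2": panel.ld_score}
    )
    df.to_csv(os.path.join(directory, "ldscores.l2.ldscore"), sep="\t", index=False)
    with open(os.path.join(directory, "ldscores.l2.M"), "w") as fh:
        fh.write(f"{panel.M}\n")


def read_ld_panel(directory: str | os.PathLike, n_blocks: int = 200) -> LDScorePanel:
    """Read an LD-score file pair written by :func:`write_ld_panel`.

    Block assignments are reconstructed as ``n_blocks`` contiguous,
    near-equal runs in file (position) order; reference alleles are unknown
    for plain LD-score files.
    """
    df = pd.read_csv(os.path.join(directory, "ldscores.l2.ldscore"), sep="\t")
    for col in ("CHR", "SNP", "BP", "L2"):
        if col not in df.columns:
            raise ValueError(f"LD score file is missing required column {col!r}")
    with open(os.path.join(directory, "ldscores.l2.M")) as fh:
        M = int(float(fh.read().split()[0]))
    m = len(df)
    block_id = np.concatenate(
        [np.full(len(part), b) for b, part in enumerate(np.array_split(np.arange(m), n_blocks))]
    )
    return LDScorePanel(
        df["SNP"].to_numpy(dtype=object),
        df["CHR"].to_numpy(dtype=int),
        df["BP"].to_numpy(dtype=int),
        df["L2"].to_numpy(dtype=float),
        M,
        block_id,
    )
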