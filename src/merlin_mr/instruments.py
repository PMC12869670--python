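"""LD-matrix estimation and dual-threshold instrument selection.

Instrument selection admits a SNP as a candidate if it reaches significance in
*either* the exposure GWAS (P < t_gwas) or the exposure GWIS (P < t_gwis) —
interaction-driven instruments are first-class citizens.  Candidates are then
greedily LD-clumped: the SNP with the smallest priority P value
(min of its GWAS and GWIS P) claims a clump and removes all remaining
candidates correlated with it above ``r2_max`` within ``window_bp``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .sumstats import HarmonizedPanel

logger = logging.getLogger(__name__)

__all__ = ["LDMatrix", "IVSelectionConfig", "estimate_ld", "select_ivs"]


@dataclass
class LDMatrix:
    """Pairwise genotype correlation matrix among instruments."""

    snp_ids: List[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.snp_ids)
        if self.r.shape != (m, m):
            raise ValueError(f"LD matrix shape {self.r.shape} does not match {m} SNPs")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("LD matrix must have unit diagonal")

    @classmethod
    def identity(cls, snp_ids: Sequence[str]) -> "LDMatrix":
        return cls(list(snp_ids), np.eye(len(snp_ids)))

    @property
    def is_identity(self) -> bool:
        return np.array_equal(self.r, np.eye(len(self.snp_ids)))

    def subset(self, snp_ids: Sequence[str]) -> "LDMatrix":
        index = {s: i for i, s in enumerate(self.snp_ids)}
        idx = np.array([index[s] for s in snp_ids])
        return LDMatrix(list(snp_ids), self.r[np.ix_(idx, idx)])

    def to_tsv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(self.r, index=self.snp_ids, columns=self.snp_ids).to_csv(path, sep="\t")


@dataclass(frozen=True)
class IVSelectionConfig:
    """Thresholds of the dual-channel selection + clumping rule."""

    t_gwas: float = 5e-8
    t_gwis: float = 5e-6
    r2_max: float = 0.3
    window_bp: float = 1_000_000

    def __post_init__(self) -> None:
        for name in ("t_gwas", "t_gwis"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.r2_max <= 1.0:
            raise ValueError(f"r2_max must lie in (0, 1], got {self.r2_max}")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be > 0")


def estimate_ld(genotypes: np.ndarray, snp_ids: Sequence[str],
                shrinkage: float = 0.05) -> LDMatrix:
    """Pearson LD matrix from a reference dosage matrix (individuals x SNPs).

    Zero-variance columns are excluded with a warning.  The raw correlation
    matrix is shrunk toward the identity, ``r <- (1 - lambda) r + lambda I``,
    so the result is strictly positive definite and safely invertible inside
    the likelihood even when the panel is small relative to the SNP count.
    """
    genotypes = np.asarray(genotypes, dtype=float)
    if genotypes.ndim != 2 or genotypes.shape[0] < 2:
        raise ValueError("need a 2-D genotype matrix with at least 2 individuals")
    if genotypes.shape[1] != len(snp_ids):
        raise ValueError("snp_ids length does not match genotype columns")
    variances = genotypes.var(axis=0)
    ok = variances > 0
    if not ok.all():
        dropped = [s for s, k in zip(snp_ids, ok) if not k]
        logger.warning("estimate_ld: excluding %d zero-variance SNP(s): %s",
                       len(dropped), ", ".join(dropped[:5]))
    kept = [s for s, k in zip(snp_ids, ok) if k]
    sub = genotypes[:, ok]
    if sub.shape[1] == 1:
        return LDMatrix(kept, np.ones((1, 1)))
    r = np.corrcoef(sub, rowvar=False)
    m = r.shape[0]
    r = (1.0 - shrinkage) * r + shrinkage * np.eye(m)
    np.fill_diagonal(r, 1.0)
    return LDMatrix(kept, r)


def select_ivs(panel: HarmonizedPanel, positions: Optional[np.ndarray],
               cfg: IVSelectionConfig, ld: Optional[LDMatrix] = None) -> List[str]:
    """Dual-threshold candidate selection followed by min-P greedy clumping.

    Returns kept SNP ids sorted by priority P (ties broken lexicographically
    by snp_id, which also makes the output independent of input row order).
    With ``ld=None`` instruments are treated as independent and clumping is a
    no-op beyond thresholding.
    """
    df = panel.df
    p1 = df["p1"].to_numpy(dtype=float)
    p2 = df["p2"].to_numpy(dtype=float)
    candidate = (p1 < cfg.t_gwas) | (p2 < cfg.t_gwis)
    if not candidate.any():
        raise ValueError(
            "no SNP passes either exposure threshold "
            f"(t_gwas={cfg.t_gwas:g}, t_gwis={cfg.t_gwis:g}); relax the thresholds")
    priority = np.minimum(p1, p2)
    snps = np.asarray(panel.snp_ids, dtype=object)

    if positions is None:
        positions = panel.positions
    pos = None if positions is None else np.asarray(positions, dtype=float)

    idx = np.flatnonzero(candidate)
    # deterministic order: (priority P, snp_id)
    order = sorted(idx, key=lambda i: (priority[i], str(snps[i])))

    if ld is None or ld.is_identity:
        return [str(snps[i]) for i in order]

    r = ld.subset(list(snps)).r  # align LD to panel order
    kept: List[str] = []
    claimed = np.zeros(len(snps), dtype=bool)
    for i in order:
        if claimed[i]:
            continue
        kept.append(str(snps[i]))
        claimed[i] = True
        for j in order:
            if claimed[j]:
                continue
            in_window = True if pos is None else abs(pos[i] - pos[j]) <= cfg.window_bp
            if in_window and r[i, j] ** 2 > cfg.r2_max:
                claimed[j] = True
    return kept
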