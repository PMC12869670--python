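"""Summary-statistics likelihood: block mean structures and Gaussian log-density.

The model approximates the joint distribution of the four observed effect
vectors by multivariate normals whose means are linear images of the true
per-SNP effects.  Writing ``S_k`` for the diagonal SE matrix of block *k* and
``R`` for the instrument LD matrix:

* exposure GWAS:   gamma_hat(G)  ~ N(S1 R S1^-1 gamma(G),  S1 R S1)
* exposure GWIS:   gamma_hat(GI) ~ N(S2 R S2^-1 gamma(GI), S2 R S2)
* outcome  GWAS:   Gamma_hat(G)  ~ N(m3, S3 R S3)
* outcome  GWIS:   Gamma_hat(GI) ~ N(m4, S4 R S4)

with the derived true effects ``Gamma(G) = beta_A gamma(G) + beta_G`` and
``Gamma(GI) = beta_A gamma(GI) + beta_I gamma(G)``.  The outcome means carry
cross-terms induced by the modifier's moments:

binary modifier (standardized Bernoulli, skewness ``mu3``):
    m3 = S3 R S3^-1 (Gamma(G) + beta_I gamma(GI))
    m4 = S4 R S4^-1 Gamma(GI) + mu3 beta_I S4^2 S3^-1 R S3^-1 gamma(GI)

continuous modifier with zero skewness:
    m3 = S3 R S3^-1 Gamma(G) + beta_I S3^2 S4^-1 R S4^-1 gamma(GI)
    m4 = S4 R S4^-1 Gamma(GI)

With independent instruments (R = I) the binary and continuous forms agree up
to SE-ratio factors that are ~1 in practice; the cross-term is the leakage of
the interaction signal into the marginal outcome GWAS that the model exploits
(and that biases classical MR when ignored).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .instruments import LDMatrix
from .modifier import ModifierSpec
from .sumstats import HarmonizedPanel

__all__ = [
    "MerlinParams",
    "exposure_block_mean",
    "outcome_gwas_mean",
    "outcome_gwis_mean",
    "log_likelihood",
    "BLOCKS",
]

BLOCKS = ("exp_gwas", "exp_gwis", "out_gwas", "out_gwis")


@dataclass
class MerlinParams:
    """Structural parameters of the joint model.

    ``Gamma(G)`` and ``Gamma(GI)`` are derived, not stored.
    """

    beta_A: float
    beta_I: float
    gamma_G: np.ndarray
    gamma_GI: np.ndarray
    beta_G: np.ndarray
    sigma2_1: float = 1.0
    sigma2_2: float = 1.0
    sigma2_3: float = 1.0

    def __post_init__(self) -> None:
        self.gamma_G = np.asarray(self.gamma_G, dtype=float)
        self.gamma_GI = np.asarray(self.gamma_GI, dtype=float)
        self.beta_G = np.asarray(self.beta_G, dtype=float)
        if not (len(self.gamma_G) == len(self.gamma_GI) == len(self.beta_G)):
            raise ValueError("effect vectors must have equal length")
        for name in ("sigma2_1", "sigma2_2", "sigma2_3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def Gamma_G(self) -> np.ndarray:
        return self.beta_A * self.gamma_G + self.beta_G

    @property
    def Gamma_GI(self) -> np.ndarray:
        return self.beta_A * self.gamma_GI + self.beta_I * self.gamma_G


def _rmat(R: Optional[LDMatrix]) -> Optional[np.ndarray]:
    if R is None or (isinstance(R, LDMatrix) and R.is_identity):
        return None
    return R.r if isinstance(R, LDMatrix) else np.asarray(R, dtype=float)


def _srs_inv_apply(s: np.ndarray, R: Optional[np.ndarray], v: np.ndarray) -> np.ndarray:
    """Compute ``S R S^-1 v`` (identity when R is None)."""
    if R is None:
        return v.copy()
    return s * (R @ (v / s))


def exposure_block_mean(gamma: np.ndarray, s: np.ndarray,
                        R: Optional[LDMatrix] = None) -> np.ndarray:
    """Mean of an exposure block: ``S R S^-1 gamma`` (covariance ``S R S``)."""
    gamma = np.asarray(gamma, dtype=float)
    s = np.asarray(s, dtype=float)
    if gamma.shape != s.shape:
        raise ValueError("gamma and s must have equal length")
    return _srs_inv_apply(s, _rmat(R), gamma)


def outcome_gwas_mean(params: MerlinParams, s3: np.ndarray, s4: np.ndarray,
                      R: Optional[LDMatrix], mod: ModifierSpec) -> np.ndarray:
    """Mean of the outcome-GWAS block (covariance ``S3 R S3``)."""
    s3 = np.asarray(s3, dtype=float)
    s4 = np.asarray(s4, dtype=float)
    Rm = _rmat(R)
    if mod.kind == "binary":
        inner = params.Gamma_G + params.beta_I * params.gamma_GI
        return _srs_inv_apply(s3, Rm, inner)
    base = _srs_inv_apply(s3, Rm, params.Gamma_G)
    v = params.beta_I * params.gamma_GI
    if Rm is None:
        cross = s3 ** 2 / s4 ** 2 * v
    else:
        cross = s3 ** 2 * ((Rm @ (v / s4)) / s4)
    return base + cross


def outcome_gwis_mean(params: MerlinParams, s3: np.ndarray, s4: np.ndarray,
                      R: Optional[LDMatrix], mod: ModifierSpec) -> np.ndarray:
    """Mean of the outcome-GWIS block (covariance ``S4 R S4``)."""
    s3 = np.asarray(s3, dtype=float)
    s4 = np.asarray(s4, dtype=float)
    Rm = _rmat(R)
    base = _srs_inv_apply(s4, Rm, params.Gamma_GI)
    if mod.kind == "continuous" or mod.mu3 == 0.0:
        return base
    v = params.beta_I * params.gamma_GI
    if Rm is None:
        cross = mod.mu3 * s4 ** 2 / s3 ** 2 * v
    else:
        cross = mod.mu3 * s4 ** 2 * ((Rm @ (v / s3)) / s3)
    return base + cross


def _block_logpdf(obs: np.ndarray, mean: np.ndarray, s: np.ndarray,
                  R: Optional[np.ndarray], R_cho=None) -> float:
    """Log-density of N(mean, S R S) at obs, via a Cholesky factor of R."""
    resid = (np.asarray(obs, dtype=float) - mean) / s
    m = len(resid)
    logdet = 2.0 * float(np.sum(np.log(s)))
    if R is None:
        quad = float(resid @ resid)
    else:
        if R_cho is None:
            R_cho = cho_factor(R, lower=True)
        L = R_cho[0]
        logdet += 2.0 * float(np.sum(np.log(np.diag(L))))
        quad = float(resid @ cho_solve(R_cho, resid))
    if not math.isfinite(quad):
        raise FloatingPointError("non-finite quadratic form in likelihood block")
    return -0.5 * (m * math.log(2.0 * math.pi) + logdet + quad)


def log_likelihood(params: MerlinParams, panel: HarmonizedPanel,
                   R: Optional[LDMatrix], mod: ModifierSpec,
                   blocks: Sequence[str] = BLOCKS) -> float:
    """Joint Gaussian log-likelihood of the requested summary-statistic blocks."""
    bad = set(blocks) - set(BLOCKS)
    if bad:
        raise ValueError(f"unknown block(s): {sorted(bad)}")
    Rm = _rmat(R)
    R_cho = cho_factor(Rm, lower=True) if Rm is not None else None
    s3, s4 = panel.s3, panel.s4
    total = 0.0
    for block in blocks:
        try:
            if block == "exp_gwas":
                mean = exposure_block_mean(params.gamma_G, panel.s1, R)
                total += _block_logpdf(panel.gamma_G, mean, panel.s1, Rm, R_cho)
            elif block == "exp_gwis":
                mean = exposure_block_mean(params.gamma_GI, panel.s2, R)
                total += _block_logpdf(panel.gamma_GI, mean, panel.s2, Rm, R_cho)
            elif block == "out_gwas":
                mean = outcome_gwas_mean(params, s3, s4, R, mod)
                total += _block_logpdf(panel.Gamma_G, mean, s3, Rm, R_cho)
            else:
                mean = outcome_gwis_mean(params, s3, s4, R, mod)
                total += _block_logpdf(panel.Gamma_GI, mean, s4, Rm, R_cho)
        except FloatingPointError as err:
            raise FloatingPointError(f"block {block}: {err}") from None
    return total
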