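"""Summary-statistics algebra for sex-stratified data.

All operations are pure functions of point estimates and standard errors and
vectorize row-wise over SNP tables.  The stratum coding convention is
Male = +1, Female = -1 (a ``coding`` flag flips the interaction sign for the
opposite convention), under which

    b_gwis = (b_M - b_F) / 2            (interaction from stratified GWAS)
    b_meta = IVW combination of b_M, b_F (sex-combined GWAS)
    beta_M = beta_A + beta_I,  beta_F = beta_A - beta_I
    beta_I = (beta_M - beta_F) / 2      (interaction from stratified causal fits)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np

from .inference import MerlinFit, wald_p

__all__ = [
    "StratifiedPair",
    "gwis_from_stratified",
    "meta_combine",
    "sex_specific_effects",
    "stratified_interaction",
]

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class StratifiedPair:
    """Stratum-specific estimates: stratum 1 = male (+1), stratum 0 = female (-1)."""

    beta_m: ArrayLike
    se_m: ArrayLike
    beta_f: ArrayLike
    se_f: ArrayLike

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.se_m) <= 0) or np.any(np.asarray(self.se_f) <= 0):
            raise ValueError("standard errors must be > 0")


def gwis_from_stratified(pair: StratifiedPair, coding: int = +1) -> Tuple[ArrayLike, ArrayLike]:
    """SNP-by-sex interaction effect derived from sex-stratified GWAS.

    Returns ``(beta, se)`` with ``beta = (b_M - b_F)/2`` and
    ``se = sqrt(se_M^2 + se_F^2)/2``.
    """
    beta = coding * 0.5 * (np.asarray(pair.beta_m) - np.asarray(pair.beta_f))
    se = 0.5 * np.sqrt(np.asarray(pair.se_m) ** 2 + np.asarray(pair.se_f) ** 2)
    return _maybe_scalar(beta), _maybe_scalar(se)


def meta_combine(pair: StratifiedPair) -> Tuple[ArrayLike, ArrayLike]:
    """Fixed-effect inverse-variance-weighted combination of the two strata."""
    wm = 1.0 / np.asarray(pair.se_m, dtype=float) ** 2
    wf = 1.0 / np.asarray(pair.se_f, dtype=float) ** 2
    beta = (np.asarray(pair.beta_m) * wm + np.asarray(pair.beta_f) * wf) / (wm + wf)
    se = (wm + wf) ** -0.5
    return _maybe_scalar(beta), _maybe_scalar(se)


def sex_specific_effects(fit: MerlinFit, coding: int = +1
                         ) -> Tuple[float, float, float, float, float, float]:
    """Reconstruct stratum-specific causal effects from a joint fit.

    Returns ``(beta_M, se_M, p_M, beta_F, se_F, p_F)``.  Standard errors come
    from the joint posterior of (beta_A, beta_I):
    ``var(beta_A) + var(beta_I) +/- 2 cov``.
    """
    bA, bI = fit.beta_A_mean, coding * fit.beta_I_mean
    vA, vI = fit.beta_A_sd ** 2, fit.beta_I_sd ** 2
    cov = coding * fit.beta_AI_cov
    beta_m = bA + bI
    beta_f = bA - bI
    se_m = float(np.sqrt(max(vA + vI + 2 * cov, 0.0)))
    se_f = float(np.sqrt(max(vA + vI - 2 * cov, 0.0)))
    return (beta_m, se_m, wald_p(beta_m, se_m) if se_m > 0 else 1.0,
            beta_f, se_f, wald_p(beta_f, se_f) if se_f > 0 else 1.0)


def stratified_interaction(pair: StratifiedPair, coding: int = +1) -> Tuple[ArrayLike, ArrayLike]:
    """Interaction implied by stratified causal estimates: ``(beta_M - beta_F)/2``."""
    return gwis_from_stratified(pair, coding=coding)


def _maybe_scalar(x):
    x = np.asarray(x)
    return float(x) if x.ndim == 0 else x
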