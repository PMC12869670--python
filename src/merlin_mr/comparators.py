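"""Classical two-sample MR baselines: IVW, MR-Egger, and sex-stratified use.

Both estimators are weighted regressions of outcome effects on exposure
effects with weights ``1/se_Gamma^2``: IVW constrains the intercept to zero
(fixed-effect variant), MR-Egger frees it to absorb directional pleiotropy
after orienting all exposure effects to be non-negative.  They target only
the average effect; their sex-stratified application recovers an interaction
as half the difference of the per-stratum estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .inference import wald_p
from .sumstats import SumstatsTable
from .transforms import StratifiedPair, stratified_interaction

logger = logging.getLogger(__name__)

__all__ = ["MrResult", "ivw", "egger", "stratified_mr"]


@dataclass
class MrResult:
    estimate: float
    se: float
    p: float
    method: str
    n_ivs: int
    intercept: Optional[float] = None
    intercept_se: Optional[float] = None


def _clean(gamma_hat, se_gamma, Gamma_hat, se_Gamma):
    g = np.asarray(gamma_hat, dtype=float)
    sg = np.asarray(se_gamma, dtype=float)
    G = np.asarray(Gamma_hat, dtype=float)
    sG = np.asarray(se_Gamma, dtype=float)
    if not (g.shape == sg.shape == G.shape == sG.shape):
        raise ValueError("input vectors must share one length")
    ok = g != 0
    if not ok.all():
        logger.warning("excluding %d SNP(s) with zero exposure effect", int((~ok).sum()))
    return g[ok], sg[ok], G[ok], sG[ok]


def ivw(gamma_hat, se_gamma, Gamma_hat, se_Gamma) -> MrResult:
    """Fixed-effect inverse-variance-weighted estimate of the causal slope.

    Equivalent to the zero-intercept weighted regression of Gamma_hat on
    gamma_hat with weights 1/se_Gamma^2.
    """
    g, _, G, sG = _clean(gamma_hat, se_gamma, Gamma_hat, se_Gamma)
    if len(g) < 1:
        raise ValueError("IVW needs at least 1 SNP with nonzero exposure effect")
    w = 1.0 / sG ** 2
    denom = float(np.sum(w * g * g))
    est = float(np.sum(w * g * G) / denom)
    se = denom ** -0.5
    return MrResult(est, se, wald_p(est, se), "IVW", n_ivs=len(g))


def egger(gamma_hat, se_gamma, Gamma_hat, se_Gamma) -> MrResult:
    """MR-Egger: weighted regression with a free pleiotropy intercept.

    Exposure/outcome pairs are sign-oriented so all gamma_hat >= 0 before the
    fit; SEs use the estimated residual scale (n - 2 df).
    """
    g, _, G, sG = _clean(gamma_hat, se_gamma, Gamma_hat, se_Gamma)
    n = len(g)
    if n < 3:
        raise ValueError("MR-Egger needs at least 3 SNPs")
    flip = np.sign(g)
    g, G = g * flip, G * flip
    w = 1.0 / sG ** 2
    sw = np.sqrt(w)
    X = np.column_stack([np.ones(n), g]) * sw[:, None]
    y = G * sw
    XtX = X.T @ X
    coef = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ coef
    sigma2 = float(resid @ resid) / (n - 2)
    cov = sigma2 * np.linalg.inv(XtX)
    a, b = float(coef[0]), float(coef[1])
    se_a, se_b = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    return MrResult(b, se_b, wald_p(b, se_b), "MR-Egger", n_ivs=n,
                    intercept=a, intercept_se=se_a)


_METHODS = {"ivw": ivw, "egger": egger}


def _stratum_fit(method: str, exp_t: SumstatsTable, out_t: SumstatsTable,
                 t_gwas: float) -> MrResult:
    exp_df = exp_t.df.set_index("snp")
    out_df = out_t.df.set_index("snp")
    shared = [s for s in exp_df.index if s in out_df.index]
    exp_df, out_df = exp_df.loc[shared], out_df.loc[shared]
    sel = exp_df["p"].to_numpy(dtype=float) < t_gwas
    if not sel.any():
        raise ValueError(f"no instrument passes P < {t_gwas:g} in this stratum")
    return _METHODS[method](
        exp_df["beta"].to_numpy()[sel], exp_df["se"].to_numpy()[sel],
        out_df["beta"].to_numpy()[sel], out_df["se"].to_numpy()[sel])


def stratified_mr(method: str, exp_m: SumstatsTable, out_m: SumstatsTable,
                  exp_f: SumstatsTable, out_f: SumstatsTable,
                  t_gwas: float = 5e-8) -> Tuple[MrResult, MrResult, MrResult]:
    """Per-stratum MR fits plus the implied interaction.

    Instruments are selected within each stratum from its own exposure GWAS at
    ``P < t_gwas``.  Returns ``(male_fit, female_fit, interaction)``; the
    interaction is half the male-female difference with independent-stratum
    SE.
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {sorted(_METHODS)}")
    fit_m = _stratum_fit(method, exp_m, out_m, t_gwas)
    fit_f = _stratum_fit(method, exp_f, out_f, t_gwas)
    pair = StratifiedPair(fit_m.estimate, fit_m.se, fit_f.estimate, fit_f.se)
    b, se = stratified_interaction(pair)
    inter = MrResult(float(b), float(se), wald_p(float(b), float(se)),
                     f"stratified-{method} interaction",
                     n_ivs=fit_m.n_ivs + fit_f.n_ivs)
    return fit_m, fit_f, inter
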