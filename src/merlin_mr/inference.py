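"""Bayesian hierarchical estimation of the average and interaction causal effects.

The sampler is a blocked Gibbs scheme over the full conditionals of the joint
summary-statistics likelihood (see :mod:`merlin_mr.likelihood`).  Per-SNP
true effects carry hierarchical normal priors: the pair
(gamma_G_j, gamma_GI_j) is bivariate normal with an unknown 2x2 covariance
(variances sigma1^2, sigma3^2 and correlation rho_prior — the polygenic
gene-environment interaction correlation), updated by a conjugate
inverse-Wishart step; pleiotropic effects beta(G) ~ N(0, sigma2^2 I) with
sigma2^2 ~ InvGamma(a, b); and improper flat priors sit on ``beta_A`` and
``beta_I``.  When the effect correlation is zero this reduces exactly to
independent N(0, sigma_k^2 I) priors on gamma(G) and gamma(GI).  Every block
mean is linear in each parameter sub-vector given the others, so all
conditionals are Gaussian; the (beta_A, beta_I) pair is updated jointly,
which is what lets the model separate an interaction-induced tilt of the
outcome GWAS from a genuine average effect.

Two execution paths share the same conditional algebra: a vectorized O(M)
path for independent instruments (R = I, the usual case after strict
clumping) and a dense-matrix path for a general LD matrix R (independent
per-vector priors there).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import stats as _stats
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .instruments import LDMatrix
from .modifier import ModifierSpec
from .sumstats import HarmonizedPanel

__all__ = ["McmcConfig", "MerlinFit", "fit_merlin", "fit_merlin_no_outcome_gwis", "wald_p"]


@dataclass(frozen=True)
class McmcConfig:
    """Gibbs sampler settings (weak InvGamma(0.01, 0.01) hyperpriors by default)."""

    n_iter: int = 5000
    n_burnin: int = 2000
    n_chains: int = 2
    seed: int = 0
    hyper_a: float = 0.01
    hyper_b: float = 0.01

    def __post_init__(self) -> None:
        if not self.n_iter > self.n_burnin >= 0:
            raise ValueError("require n_iter > n_burnin >= 0")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")


def wald_p(mean: float, sd: float) -> float:
    """Two-sided normal P value for mean/sd."""
    if sd <= 0:
        raise ValueError("sd must be > 0")
    return float(2.0 * _stats.norm.sf(abs(mean / sd)))


@dataclass
class MerlinFit:
    """Posterior summaries for the causal parameters plus retained draws."""

    beta_A_mean: float
    beta_A_sd: float
    beta_A_ci95: Tuple[float, float]
    beta_A_p: float
    beta_I_mean: float
    beta_I_sd: float
    beta_I_ci95: Tuple[float, float]
    beta_I_p: float
    beta_AI_cov: float
    sigma2_means: Dict[str, float]
    error_corr_means: Dict[str, float]
    rhat: Dict[str, float]
    chains: Dict[str, np.ndarray] = field(repr=False)
    n_snps: int = 0
    experimental: bool = False
    warnings: List[str] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return all(r <= 1.1 for r in self.rhat.values() if math.isfinite(r))

    def to_dict(self) -> dict:
        return {
            "beta_A": {"mean": self.beta_A_mean, "sd": self.beta_A_sd,
                       "ci95": list(self.beta_A_ci95), "p": self.beta_A_p},
            "beta_I": {"mean": self.beta_I_mean, "sd": self.beta_I_sd,
                       "ci95": list(self.beta_I_ci95), "p": self.beta_I_p},
            "beta_AI_cov": self.beta_AI_cov,
            "sigma2_means": self.sigma2_means,
            "error_corr_means": self.error_corr_means,
            "rhat": self.rhat,
            "n_snps": self.n_snps,
            "experimental": self.experimental,
            "warnings": self.warnings,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# chain runners
# ---------------------------------------------------------------------------

def _cross_ratios(s3: np.ndarray, s4: np.ndarray, mod: ModifierSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Per-SNP coefficients (t3, t4) of the modifier cross-terms for R = I.

    t3 multiplies ``beta_I * gamma_GI`` in the outcome-GWAS mean, t4 in the
    outcome-GWIS mean.
    """
    if mod.kind == "binary":
        t3 = np.ones_like(s3)
        t4 = mod.mu3 * s4 ** 2 / s3 ** 2
    else:
        t3 = s3 ** 2 / s4 ** 2
        t4 = np.zeros_like(s4)
    return t3, t4


def _init_state(z1, z2, z3, z4, i3, include4: bool) -> dict:
    """Moment-based starting values; overdispersed sigma2's avoid funnel sticking."""
    denom = float(np.sum(z1 * z1 * i3))
    beta_A0 = float(np.sum(z1 * z3 * i3) / denom) if denom > 0 else 0.0
    beta_G0 = z3 - beta_A0 * z1
    return {
        "gamma_G": z1.copy(),
        "gamma_GI": z2.copy(),
        "beta_G": beta_G0,
        "beta_A": beta_A0,
        "beta_I": 0.0,
        "sigma2_1": max(float(np.mean(z1 ** 2)), 1e-8),
        "sigma2_2": max(float(np.mean(beta_G0 ** 2)), 1e-8),
        "sigma2_3": max(float(np.mean(z2 ** 2)), 1e-8),
    }


def _draw_invgamma(rng, shape: float, scale: float) -> float:
    return float(scale / rng.gamma(shape))


def _sample_bivariate(z1, z2, P11, P12, P22, b1, b2) -> Tuple[float, float]:
    """Draw from N(P^-1 b, P^-1) for a 2x2 precision P (tiny jitter for safety)."""
    P11 += 1e-12
    P22 += 1e-12
    L11 = math.sqrt(P11)
    L21 = P12 / L11
    L22sq = P22 - L21 * L21
    L22 = math.sqrt(max(L22sq, 1e-14 * P22 + 1e-300))
    y1 = b1 / L11
    y2 = (b2 - L21 * y1) / L22
    mu2 = y2 / L22
    mu1 = (y1 - L21 * mu2) / L11
    w2 = z2 / L22
    w1 = (z1 - L21 * w2) / L11
    return mu1 + w1, mu2 + w2


_RHO_GRID = np.linspace(-0.95, 0.95, 191)
_RHO_LOGDET = -0.5 * np.log1p(-_RHO_GRID ** 2)   # per-SNP -1/2 log(1 - rho^2)
_RHO_D = 1.0 / (1.0 - _RHO_GRID ** 2)


def _draw_rho(u: float, M: int, A: float, B: float, C: float) -> float:
    """Griddy-Gibbs draw of an error correlation from its conditional.

    (A, B, C) are the sufficient statistics (sum u1^2, sum u1 u2, sum u2^2) of
    the standardized residual pairs; the prior is uniform on the grid and the
    draw inverts the discretized conditional CDF at ``u``.
    """
    ll = M * _RHO_LOGDET - 0.5 * _RHO_D * (A - 2.0 * _RHO_GRID * B + C)
    ll -= ll.max()
    w = np.exp(ll)
    cdf = np.cumsum(w)
    idx = int(np.searchsorted(cdf, u * cdf[-1]))
    return float(_RHO_GRID[min(idx, len(_RHO_GRID) - 1)])


def _error_weight_vectors(P_err, svec, include4):
    """Per-SNP entries of the inverse 4x4 error covariance.

    ``P_err`` is the cross-block error CORRELATION matrix (unit diagonal);
    per SNP the error covariance is diag(s) P diag(s), so its inverse has
    entries Pinv[a,b] / (s_a s_b).  Returns a 4x4 list-of-lists with vector
    entries, ``None`` marking structural zeros (skipped by the updates).
    """
    act = (0, 1, 2, 3) if include4 else (0, 1, 2)
    Pi = np.zeros((4, 4))
    sub = np.linalg.inv(P_err[np.ix_(act, act)])
    Pi[np.ix_(act, act)] = sub
    W = [[None] * 4 for _ in range(4)]
    for a in range(4):
        for b in range(4):
            if Pi[a, b] != 0.0:
                W[a][b] = Pi[a, b] / (svec[a] * svec[b])
    return W


def _wdot(W, a, r):
    """q_a = sum_b W[a][b] r[b], skipping structural zeros."""
    q = None
    for b in range(4):
        if W[a][b] is not None:
            term = W[a][b] * r[b]
            q = term if q is None else q + term
    return q if q is not None else 0.0


def _chain_identity(z1, z2, z3, z4, s1, s2, s3, s4, t3, t4, include4, fix_beta_I,
                    estimate_corr, P_err, cfg: McmcConfig, rng) -> Dict[str, np.ndarray]:
    """Gibbs chain for independent instruments (conditionals per-SNP, vectorized).

    Two structural features beyond a naive four-independent-blocks scheme:

    * the per-SNP effect pair (gamma_G_j, gamma_GI_j) gets a joint bivariate
      normal prior whose 2x2 covariance (variances sigma1^2, sigma3^2 and the
      effect correlation rho_prior — the polygenic gene-environment
      interaction) is sampled by a conjugate inverse-Wishart update;
    * the sampling errors of the four observed statistics for one SNP may be
      correlated across blocks through the 4x4 correlation matrix ``P_err``
      (overlapping GWAS/GWIS cohorts within a trait; shared individuals
      between the exposure and outcome cohorts).  With ``estimate_corr`` the
      two within-trait entries are sampled by griddy-Gibbs instead.

    With identity ``P_err`` and zero effect correlation the scheme reduces
    exactly to four independent blocks with independent priors.
    """
    M = len(z1)
    svec = (s1, s2, s3, s4)
    i3 = 1.0 / s3 ** 2
    st = _init_state(z1, z2, z3, z4, i3, include4)
    gG, gGI, bG = st["gamma_G"], st["gamma_GI"], st["beta_G"]
    bA, bI = st["beta_A"], st["beta_I"]
    s2_2 = st["sigma2_2"]
    # prior precision of the (gamma_G, gamma_GI) pair, initialized from moments
    p11, p22, p12 = 1.0 / st["sigma2_1"], 1.0 / st["sigma2_3"], 0.0
    sig1, sig3, rho_p = st["sigma2_1"], st["sigma2_3"], 0.0
    a0, b0 = cfg.hyper_a, cfg.hyper_b
    nu0, psi0 = 3.0, 1e-8
    P_err = np.array(P_err, dtype=float)
    rhoE, rhoO = float(P_err[0, 1]), float(P_err[2, 3])
    W = _error_weight_vectors(P_err, svec, include4)

    keep = cfg.n_iter - cfg.n_burnin
    out = {k: np.empty(keep) for k in ("beta_A", "beta_I", "sigma2_1", "sigma2_2",
                                       "sigma2_3", "rho_prior", "rho_E", "rho_O")}

    # pre-generate every draw: the inner loop then runs pure vector arithmetic
    Zvec = rng.standard_normal((cfg.n_iter, 3, M))
    Zbiv = rng.standard_normal((cfg.n_iter, 2))
    Zgam = rng.gamma(a0 + 0.5 * M, size=cfg.n_iter)
    nu = nu0 + M
    Zchi1 = rng.chisquare(nu, size=cfg.n_iter)
    Zchi2 = rng.chisquare(nu - 1.0, size=cfg.n_iter)
    Zwis = rng.standard_normal(cfg.n_iter)
    Zrho = rng.random((cfg.n_iter, 2))

    zeros = np.zeros(M)
    ones = np.ones(M)

    for it in range(cfg.n_iter):
        cO = bA + bI * t4

        # joint (gamma_G, gamma_GI) pair update, vectorized 2x2 per SNP.
        # Design C maps the pair into the four block means:
        # rows (z1..z4), columns (gamma_G, gamma_GI):
        #   C = [[1, 0], [0, 1], [bA, bI t3], [bI, bA + bI t4]]
        c0 = (ones, zeros, bA * ones, bI * ones)
        c1 = (zeros, ones, bI * t3, cO)
        r = (z1, z2, z3 - bG, z4)
        q = [_wdot(W, a, r) for a in range(4)]
        P11 = p11
        P12v = p12
        P22 = p22
        b1 = 0.0
        b2 = 0.0
        for a in range(4):
            b1 = b1 + c0[a] * q[a]
            b2 = b2 + c1[a] * q[a]
            for b in range(4):
                if W[a][b] is None:
                    continue
                P11 = P11 + c0[a] * c0[b] * W[a][b]
                P12v = P12v + c0[a] * c1[b] * W[a][b]
                P22 = P22 + c1[a] * c1[b] * W[a][b]
        L11 = np.sqrt(P11)
        L21 = P12v / L11
        L22 = np.sqrt(np.maximum(P22 - L21 * L21, 1e-300))
        y1 = b1 / L11
        y2 = (b2 - L21 * y1) / L22
        mu2 = y2 / L22
        mu1 = (y1 - L21 * mu2) / L11
        e2 = Zvec[it, 1] / L22
        e1 = (Zvec[it, 0] - L21 * e2) / L11
        gG = mu1 + e1
        gGI = mu2 + e2

        # beta(G): appears only in the z3 mean, coefficient 1
        m4 = bA * gGI + bI * (gG + t4 * gGI)
        r = (z1 - gG, z2 - gGI, z3 - bA * gG - bI * t3 * gGI, z4 - m4)
        prec = W[2][2] + 1.0 / s2_2
        b = _wdot(W, 2, r)
        bG = b / prec + Zvec[it, 2] / np.sqrt(prec)

        # (beta_A, beta_I) jointly, flat prior.  Coefficient 4-vectors:
        #   means = bA * A + bI * Ev + const
        A = (zeros, zeros, gG, gGI)
        Ev = (zeros, zeros, t3 * gGI, gG + t4 * gGI)
        r = (z1 - gG, z2 - gGI, z3 - bG, z4)
        q = [_wdot(W, a, r) for a in range(4)]
        vP11 = vP12 = vP22 = 0.0
        vb1 = vb2 = 0.0
        for a in (2, 3):
            vb1 = vb1 + A[a] * q[a]
            vb2 = vb2 + Ev[a] * q[a]
            for b in (2, 3):
                if W[a][b] is None:
                    continue
                vP11 = vP11 + A[a] * A[b] * W[a][b]
                vP12 = vP12 + A[a] * Ev[b] * W[a][b]
                vP22 = vP22 + Ev[a] * Ev[b] * W[a][b]
        P11s = float(np.sum(vP11))
        P12s = float(np.sum(vP12))
        P22s = float(np.sum(vP22))
        b1s = float(np.sum(vb1))
        b2s = float(np.sum(vb2))
        if fix_beta_I:
            bA = b1s / (P11s + 1e-12) + float(Zbiv[it, 0]) / math.sqrt(P11s + 1e-12)
            bI = 0.0
        else:
            bA, bI = _sample_bivariate(float(Zbiv[it, 0]), float(Zbiv[it, 1]),
                                       P11s, P12s, P22s, b1s, b2s)

        # pleiotropy variance: conjugate inverse-gamma
        s2_2 = (b0 + 0.5 * float(np.sum(bG ** 2))) / Zgam[it]

        # effect-pair prior covariance: conjugate inverse-Wishart via Bartlett.
        # Psi = Psi0 + sum_j (gG_j, gGI_j)(gG_j, gGI_j)^T ; the Wishart draw of
        # the PRECISION is what the pair update consumes directly.
        Sp = psi0 + float(gG @ gG)
        Sq = float(gG @ gGI)
        Sr = psi0 + float(gGI @ gGI)
        detPsi = Sp * Sr - Sq * Sq
        th11, th12, th22 = Sr / detPsi, -Sq / detPsi, Sp / detPsi
        l11 = math.sqrt(th11)
        l21 = th12 / l11
        l22 = math.sqrt(max(th22 - l21 * l21, 1e-300))
        a11 = math.sqrt(Zchi1[it])
        a21 = float(Zwis[it])
        a22 = math.sqrt(Zchi2[it])
        b11 = l11 * a11
        b21 = l21 * a11 + l22 * a21
        b22 = l22 * a22
        p11 = b11 * b11
        p12 = b11 * b21
        p22 = b21 * b21 + b22 * b22
        detS = p11 * p22 - p12 * p12
        sig1, sig3 = p22 / detS, p11 / detS
        rho_p = -p12 / math.sqrt(p11 * p22)

        # within-trait error correlations from standardized residual pairs
        # (only meaningful when the cross-cohort entries of P_err are zero)
        if estimate_corr:
            u1, u2 = (z1 - gG) / s1, (z2 - gGI) / s2
            rhoE = _draw_rho(float(Zrho[it, 0]), M, float(u1 @ u1), float(u1 @ u2),
                             float(u2 @ u2))
            P_err[0, 1] = P_err[1, 0] = rhoE
            if include4:
                m3 = bA * gG + bG + bI * t3 * gGI
                m4 = bA * gGI + bI * (gG + t4 * gGI)
                u3, u4 = (z3 - m3) / s3, (z4 - m4) / s4
                rhoO = _draw_rho(float(Zrho[it, 1]), M, float(u3 @ u3), float(u3 @ u4),
                                 float(u4 @ u4))
                P_err[2, 3] = P_err[3, 2] = rhoO
            W = _error_weight_vectors(P_err, svec, include4)

        k = it - cfg.n_burnin
        if k >= 0:
            out["beta_A"][k] = bA
            out["beta_I"][k] = bI
            out["sigma2_1"][k] = sig1
            out["sigma2_2"][k] = s2_2
            out["sigma2_3"][k] = sig3
            out["rho_prior"][k] = rho_p
            out["rho_E"][k] = rhoE
            out["rho_O"][k] = rhoO
    return out


def _draw_mvn_from_precision(rng, P: np.ndarray, b: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(P)
    y = solve_triangular(L, b, lower=True)
    mu = solve_triangular(L.T, y, lower=False)
    return mu + solve_triangular(L.T, rng.standard_normal(len(b)), lower=False)


def _chain_dense(z1, z2, z3, z4, s1, s2, s3, s4, Rm, mod: ModifierSpec,
                 include4, fix_beta_I, cfg: McmcConfig, rng) -> Dict[str, np.ndarray]:
    """Gibbs chain for a general LD matrix R (dense conditionals)."""
    M = len(z1)
    I = np.eye(M)
    cho_R = cho_factor(Rm, lower=True)
    R_inv = cho_solve(cho_R, I)

    def d(v):
        return v[:, None]

    i1, i2, i3, i4 = 1.0 / s1 ** 2, 1.0 / s2 ** 2, 1.0 / s3 ** 2, 1.0 / s4 ** 2
    Q1 = Rm / np.outer(s1, s1)
    Q2 = Rm / np.outer(s2, s2)
    Q3 = Rm / np.outer(s3, s3)
    Q4 = Rm / np.outer(s4, s4)
    Om3 = R_inv / np.outer(s3, s3)
    Om4 = R_inv / np.outer(s4, s4)
    W3 = d(s3) * Rm / s3[None, :]
    W4 = d(s4) * Rm / s4[None, :]
    if mod.kind == "binary":
        T3 = W3
        T4 = mod.mu3 * d(s4 ** 2) * (Rm / np.outer(s3, s3))
    else:
        T3 = d(s3 ** 2) * (Rm / np.outer(s4, s4))
        T4 = np.zeros((M, M))
    E3 = T3.T @ Om3          # T3' Omega3
    A33 = E3 @ T3
    E4 = T4.T @ Om4
    D44 = E4 @ T4
    B4 = d(i4) * T4          # W4' Omega4 T4

    st = _init_state(z1, z2, z3, z4, i3, include4)
    gG, gGI, bG = st["gamma_G"], st["gamma_GI"], st["beta_G"]
    bA, bI = st["beta_A"], st["beta_I"]
    s2_1, s2_2, s2_3 = st["sigma2_1"], st["sigma2_2"], st["sigma2_3"]
    a0, b0 = cfg.hyper_a, cfg.hyper_b

    keep = cfg.n_iter - cfg.n_burnin
    out = {k: np.empty(keep) for k in ("beta_A", "beta_I", "sigma2_1", "sigma2_2", "sigma2_3")}

    for it in range(cfg.n_iter):
        # gamma(G)
        P = Q1 + (bA * bA) * Q3 + I / s2_1
        b = i1 * z1 + bA * i3 * (z3 - W3 @ bG - bI * (T3 @ gGI))
        if include4:
            P = P + (bI * bI) * Q4
            b = b + bI * i4 * (z4 - bA * (W4 @ gGI) - bI * (T4 @ gGI))
        gG = _draw_mvn_from_precision(rng, P, b)

        # gamma(GI)
        P = Q2 + (bI * bI) * A33 + I / s2_3
        b = i2 * z2 + bI * (E3 @ (z3 - W3 @ (bA * gG + bG)))
        if include4:
            P = P + (bA * bA) * Q4 + bA * bI * (B4 + B4.T) + (bI * bI) * D44
            v = z4 - bI * (W4 @ gG)
            b = b + bA * (i4 * v) + bI * (E4 @ v)
        gGI = _draw_mvn_from_precision(rng, P, b)

        # beta(G)
        P = Q3 + I / s2_2
        b = i3 * (z3 - bA * (W3 @ gG) - bI * (T3 @ gGI))
        bG = _draw_mvn_from_precision(rng, P, b)

        # (beta_A, beta_I)
        u3A, u3I, r3 = W3 @ gG, T3 @ gGI, z3 - W3 @ bG
        P11 = float(u3A @ (Om3 @ u3A))
        P12 = float(u3A @ (Om3 @ u3I))
        P22 = float(u3I @ (Om3 @ u3I))
        b1 = float(u3A @ (Om3 @ r3))
        b2 = float(u3I @ (Om3 @ r3))
        if include4:
            u4A = W4 @ gGI
            u4I = W4 @ gG + T4 @ gGI
            P11 += float(u4A @ (Om4 @ u4A))
            P12 += float(u4A @ (Om4 @ u4I))
            P22 += float(u4I @ (Om4 @ u4I))
            b1 += float(u4A @ (Om4 @ z4))
            b2 += float(u4I @ (Om4 @ z4))
        if fix_beta_I:
            bA = b1 / (P11 + 1e-12) + float(rng.standard_normal()) / math.sqrt(P11 + 1e-12)
            bI = 0.0
        else:
            zb = rng.standard_normal(2)
            bA, bI = _sample_bivariate(float(zb[0]), float(zb[1]), P11, P12, P22, b1, b2)

        s2_1 = _draw_invgamma(rng, a0 + 0.5 * M, b0 + 0.5 * float(gG @ gG))
        s2_2 = _draw_invgamma(rng, a0 + 0.5 * M, b0 + 0.5 * float(bG @ bG))
        s2_3 = _draw_invgamma(rng, a0 + 0.5 * M, b0 + 0.5 * float(gGI @ gGI))

        k = it - cfg.n_burnin
        if k >= 0:
            out["beta_A"][k] = bA
            out["beta_I"][k] = bI
            out["sigma2_1"][k] = s2_1
            out["sigma2_2"][k] = s2_2
            out["sigma2_3"][k] = s2_3
    return out


# ---------------------------------------------------------------------------
# diagnostics and summaries
# ---------------------------------------------------------------------------

def _split_rhat(chains: List[np.ndarray]) -> float:
    """Split-Rhat potential scale reduction over one parameter's chains."""
    halves = []
    for c in chains:
        h = len(c) // 2
        if h < 2:
            return float("nan")
        halves.extend([c[:h], c[h:2 * h]])
    L = min(len(h) for h in halves)
    seg = np.stack([h[:L] for h in halves])
    W = seg.var(axis=1, ddof=1).mean()
    B = L * seg.mean(axis=1).var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (L - 1) / L * W + B / L
    return float(math.sqrt(var_plus / W))


def _summarize(chain_draws: List[Dict[str, np.ndarray]], n_snps: int,
               experimental: bool) -> MerlinFit:
    pooled = {k: np.concatenate([c[k] for c in chain_draws]) for k in chain_draws[0]}
    bA, bI = pooled["beta_A"], pooled["beta_I"]
    warn: List[str] = []

    def ci(x):
        lo, hi = np.quantile(x, [0.025, 0.975])
        return (float(lo), float(hi))

    sd_A = float(bA.std(ddof=1))
    sd_I = float(bI.std(ddof=1))
    fixed_I = np.allclose(bI, bI[0])
    rhat = {"beta_A": _split_rhat([c["beta_A"] for c in chain_draws])}
    if not fixed_I:
        rhat["beta_I"] = _split_rhat([c["beta_I"] for c in chain_draws])
    if any(r > 1.1 for r in rhat.values() if math.isfinite(r)):
        warn.append("convergence: split-Rhat > 1.1; consider more iterations")
    fit = MerlinFit(
        beta_A_mean=float(bA.mean()), beta_A_sd=sd_A, beta_A_ci95=ci(bA),
        beta_A_p=wald_p(float(bA.mean()), sd_A) if sd_A > 0 else 1.0,
        beta_I_mean=float(bI.mean()), beta_I_sd=sd_I, beta_I_ci95=ci(bI),
        beta_I_p=wald_p(float(bI.mean()), sd_I) if sd_I > 0 else 1.0,
        beta_AI_cov=float(np.cov(bA, bI)[0, 1]) if not fixed_I else 0.0,
        sigma2_means={k: float(pooled[k].mean()) for k in ("sigma2_1", "sigma2_2", "sigma2_3")},
        error_corr_means={k: float(pooled[k].mean())
                          for k in ("rho_E", "rho_O", "rho_prior") if k in pooled},
        rhat=rhat,
        chains=pooled,
        n_snps=n_snps,
        experimental=experimental,
        warnings=warn,
    )
    return fit


def _fit(panel: HarmonizedPanel, R: Optional[LDMatrix], mod: ModifierSpec,
         cfg: McmcConfig, include4: bool, fix_beta_I: bool = False,
         error_corr: str = "zero") -> MerlinFit:
    if len(panel) < 2:
        raise ValueError("need at least 2 SNPs to fit the joint model")
    P_err = np.eye(4)
    estimate_corr = False
    if isinstance(error_corr, np.ndarray) or (isinstance(error_corr, (tuple, list))
                                              and np.shape(error_corr) == (4, 4)):
        P_err = np.array(error_corr, dtype=float)
        if P_err.shape != (4, 4) or not np.allclose(np.diag(P_err), 1.0):
            raise ValueError("error_corr matrix must be 4x4 with unit diagonal")
        off = ~np.eye(4, dtype=bool)
        P_err[off] = np.clip(P_err[off], -0.95, 0.95)
        P_err = 0.5 * (P_err + P_err.T)
        evals = np.linalg.eigvalsh(P_err)
        if evals.min() <= 1e-8:   # shrink toward identity until PD
            lam = min(1.0, (1e-6 - evals.min()) / (1.0 - evals.min()))
            P_err = (1 - lam) * P_err + lam * np.eye(4)
    elif isinstance(error_corr, (tuple, list)):
        rE = float(np.clip(error_corr[0], -0.95, 0.95))
        rO = float(np.clip(error_corr[1], -0.95, 0.95))
        P_err[0, 1] = P_err[1, 0] = rE
        P_err[2, 3] = P_err[3, 2] = rO
    elif error_corr == "estimate":
        estimate_corr = True
    elif error_corr != "zero":
        raise ValueError("error_corr must be 'estimate', 'zero', a (rho_E, rho_O) pair "
                         "or a 4x4 correlation matrix")
    z1, z2, z3, z4 = panel.gamma_G, panel.gamma_GI, panel.Gamma_G, panel.Gamma_GI
    s1, s2, s3, s4 = panel.s1, panel.s2, panel.s3, panel.s4
    if np.allclose(z1, 0) and np.allclose(z2, 0):
        warnings.warn("degenerate panel: all exposure effects are zero", RuntimeWarning)

    Rm = None
    if R is not None and not R.is_identity:
        Rm = R.subset(panel.snp_ids).r

    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    chain_draws = []
    for ss in seeds:
        rng = np.random.Generator(np.random.PCG64(ss))
        if Rm is None:
            t3, t4 = _cross_ratios(s3, s4, mod)
            chain_draws.append(_chain_identity(z1, z2, z3, z4, s1, s2, s3, s4,
                                               t3, t4, include4, fix_beta_I,
                                               estimate_corr, P_err, cfg, rng))
        else:
            chain_draws.append(_chain_dense(z1, z2, z3, z4, s1, s2, s3, s4,
                                            Rm, mod, include4, fix_beta_I, cfg, rng))
    fit = _summarize(chain_draws, len(panel), experimental=not include4)
    if not include4 and fit.beta_I_sd > 0.5:
        fit.warnings.append(
            "beta_I weakly identified without the outcome GWIS block (posterior sd "
            f"{fit.beta_I_sd:.3g}); interpret with caution")
    return fit


def fit_merlin(panel: HarmonizedPanel, R: Optional[LDMatrix] = None,
               mod: Optional[ModifierSpec] = None, cfg: Optional[McmcConfig] = None,
               fix_beta_I: bool = False, error_corr: str = "zero") -> MerlinFit:
    """Fit the full four-block model by blocked Gibbs sampling.

    Parameters
    ----------
    panel:
        Harmonized four-way summary statistics.
    R:
        Instrument LD matrix; ``None`` means independent instruments.
    mod:
        Modifier specification; defaults to a balanced binary modifier.
    cfg:
        MCMC settings.
    fix_beta_I:
        Pin the interaction at zero (classical-MR reduction, mainly for
        validation).
    error_corr:
        Treatment of the per-trait correlation between the sampling errors of
        a trait's GWAS and GWIS estimates, which is nonzero whenever the two
        analyses share individuals.  ``"zero"`` (default) assumes four
        independent blocks; a ``(rho_E, rho_O)`` pair fixes the exposure and
        outcome correlations at known values (e.g. derived from the cohort
        design or a genome-wide cross-statistic intercept); a full 4x4
        correlation matrix additionally covers exposure-outcome sample
        overlap (order: exposure GWAS, exposure GWIS, outcome GWAS, outcome
        GWIS); ``"estimate"`` samples the two within-trait entries by
        griddy-Gibbs, but they are only weakly identified from the
        instruments alone.  Only the independent-instrument path supports
        nonzero values.
    """
    mod = mod or ModifierSpec.binary(0.5)
    cfg = cfg or McmcConfig()
    return _fit(panel, R, mod, cfg, include4=True, fix_beta_I=fix_beta_I,
                error_corr=error_corr)


def fit_merlin_no_outcome_gwis(panel: HarmonizedPanel, R: Optional[LDMatrix] = None,
                               mod: Optional[ModifierSpec] = None,
                               cfg: Optional[McmcConfig] = None,
                               error_corr: str = "zero") -> MerlinFit:
    """Fit without the outcome-GWIS block (flagged ``experimental``).

    The interaction is then identified only through the ``beta_I gamma(GI)``
    leakage term in the outcome-GWAS mean, so it needs a nonzero exposure
    interaction signal and comes with a wider posterior.
    """
    mod = mod or ModifierSpec.binary(0.5)
    cfg = cfg or McmcConfig()
    return _fit(panel, R, mod, cfg, include4=False, error_corr=error_corr)
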