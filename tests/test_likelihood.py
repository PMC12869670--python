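"""Block mean structures and the joint Gaussian log-likelihood.

The centrepiece is the moment-structure oracle: per-SNP GWAS/GWIS regression
coefficients from one large simulated cohort must agree with the likelihood's
mean structure evaluated at the true parameters, for every modifier preset
(balanced binary, unbalanced binary with its skewness term, continuous).
"""

import math

import numpy as np
import pytest
from scipy import stats

import merlin_mr as mm
from merlin_mr.likelihood import (BLOCKS, MerlinParams, exposure_block_mean,
                                  log_likelihood, outcome_gwas_mean, outcome_gwis_mean)


def _params(m=3, beta_A=0.0, beta_I=0.0, gamma_GI=None, gamma_G=None, beta_G=None):
    for v in (gamma_G, gamma_GI, beta_G):
        if v is not None:
            m = len(v)
    return MerlinParams(
        beta_A=beta_A, beta_I=beta_I,
        gamma_G=np.zeros(m) if gamma_G is None else np.asarray(gamma_G, float),
        gamma_GI=np.zeros(m) if gamma_GI is None else np.asarray(gamma_GI, float),
        beta_G=np.zeros(m) if beta_G is None else np.asarray(beta_G, float))


# ---------------------------------------------------------------------------
# closed-form block means
# ---------------------------------------------------------------------------

def test_exposure_mean_identity_ld():
    gamma = np.array([0.1, -0.2, 0.0])
    s = np.array([0.01, 0.02, 0.03])
    np.testing.assert_allclose(exposure_block_mean(gamma, s, None), gamma)
    np.testing.assert_allclose(exposure_block_mean(np.zeros(3), s, None), 0.0)


def test_exposure_mean_two_snp_hand_expansion():
    """S R S^-1 gamma elementwise: s_i sum_j r_ij gamma_j / s_j."""
    gamma = np.array([0.1, 0.3])
    s = np.array([0.01, 0.05])
    R = mm.LDMatrix(["a", "b"], np.array([[1.0, 0.5], [0.5, 1.0]]))
    got = exposure_block_mean(gamma, s, R)
    want = np.array([
        s[0] * (gamma[0] / s[0] + 0.5 * gamma[1] / s[1]),
        s[1] * (0.5 * gamma[0] / s[0] + gamma[1] / s[1]),
    ])
    np.testing.assert_allclose(got, want)


def test_outcome_gwas_mean_direct_substitution():
    # beta_A=0, beta_G=0, beta_I=0.3, gamma_GI=0.2 -> mean 0.06 per SNP
    p = _params(beta_I=0.3, gamma_GI=[0.2] * 3)
    s = np.ones(3)
    got = outcome_gwas_mean(p, s, s, None, mm.ModifierSpec.binary(0.5))
    np.testing.assert_allclose(got, 0.06)


def test_outcome_gwas_mean_interaction_free_limit():
    p = _params(beta_A=0.4, gamma_G=[0.1, 0.2, 0.3], beta_G=[0.01, 0.0, -0.01])
    s3, s4 = np.full(3, 0.01), np.full(3, 0.03)
    for mod in (mm.ModifierSpec.binary(0.5), mm.ModifierSpec.continuous()):
        np.testing.assert_allclose(outcome_gwas_mean(p, s3, s4, None, mod), p.Gamma_G)


def test_outcome_gwas_mean_binary_equals_continuous_when_s3_eq_s4():
    p = _params(beta_A=0.2, beta_I=0.3, gamma_G=[0.1, -0.1], gamma_GI=[0.05, 0.2])
    s = np.array([0.01, 0.02])
    b = outcome_gwas_mean(p, s, s, None, mm.ModifierSpec.binary(0.5))
    c = outcome_gwas_mean(p, s, s, None, mm.ModifierSpec.continuous())
    np.testing.assert_allclose(b, c)


def test_outcome_gwis_mean_balanced_equals_continuous():
    p = _params(beta_A=0.2, beta_I=0.3, gamma_G=[0.1, -0.1], gamma_GI=[0.05, 0.2])
    s3, s4 = np.array([0.01, 0.02]), np.array([0.02, 0.01])
    b = outcome_gwis_mean(p, s3, s4, None, mm.ModifierSpec.binary(0.5))
    c = outcome_gwis_mean(p, s3, s4, None, mm.ModifierSpec.continuous())
    np.testing.assert_allclose(b, c)


def test_outcome_gwis_mean_null_model():
    p = _params()
    s = np.ones(3)
    np.testing.assert_allclose(
        outcome_gwis_mean(p, s, s, None, mm.ModifierSpec.binary(0.25)), 0.0)


def test_outcome_gwis_mean_mu3_term():
    p = _params(beta_I=0.3, gamma_GI=[0.2, 0.2], gamma_G=[0.1, 0.1])
    s3 = np.array([0.01, 0.02])
    s4 = np.array([0.015, 0.025])
    mod = mm.ModifierSpec.binary(0.25)
    got = outcome_gwis_mean(p, s3, s4, None, mod)
    want = p.Gamma_GI + mod.mu3 * 0.3 * (s4 ** 2 / s3 ** 2) * np.asarray(p.gamma_GI)
    np.testing.assert_allclose(got, want)


# ---------------------------------------------------------------------------
# log-likelihood
# ---------------------------------------------------------------------------

def _panel_at(params, mod, s=1.0, m=4):
    sv = np.full(m, s)
    return mm.HarmonizedPanel.from_arrays(
        [f"rs{i}" for i in range(m)],
        exposure_block_mean(params.gamma_G, sv, None), sv,
        exposure_block_mean(params.gamma_GI, sv, None), sv,
        outcome_gwas_mean(params, sv, sv, None, mod), sv,
        outcome_gwis_mean(params, sv, sv, None, mod), sv)


def test_loglik_at_mean_unit_se():
    m = 4
    p = _params(m, beta_A=0.1, beta_I=0.2, gamma_G=[0.1] * m, gamma_GI=[0.05] * m)
    mod = mm.ModifierSpec.binary(0.5)
    panel = _panel_at(p, mod, s=1.0, m=m)
    ll = log_likelihood(p, panel, None, mod)
    assert ll == pytest.approx(-(4 * m / 2) * math.log(2 * math.pi))


def test_loglik_decreases_under_perturbation():
    m = 4
    p = _params(m, beta_A=0.1, gamma_G=[0.1] * m)
    mod = mm.ModifierSpec.binary(0.5)
    panel = _panel_at(p, mod, m=m)
    base = log_likelihood(p, panel, None, mod)
    panel.df.loc[0, "Gamma_G"] += 0.5
    assert log_likelihood(p, panel, None, mod) < base


def test_loglik_matches_scipy_mvn_oracle(rng):
    """Dense-LD log-density equals a generic multivariate-normal evaluation."""
    m = 5
    A = rng.normal(size=(m, m))
    R = A @ A.T
    d = np.sqrt(np.diag(R))
    R = R / np.outer(d, d)
    ld = mm.LDMatrix([f"rs{i}" for i in range(m)], R)
    p = _params(m, beta_A=0.3, beta_I=0.1,
                gamma_G=rng.normal(0, 0.1, m), gamma_GI=rng.normal(0, 0.1, m),
                beta_G=rng.normal(0, 0.02, m))
    mod = mm.ModifierSpec.binary(0.25)
    svs = [rng.uniform(0.01, 0.05, m) for _ in range(4)]
    obs = [rng.normal(0, 0.1, m) for _ in range(4)]
    panel = mm.HarmonizedPanel.from_arrays(
        ld.snp_ids, obs[0], svs[0], obs[1], svs[1], obs[2], svs[2], obs[3], svs[3])
    got = log_likelihood(p, panel, ld, mod)
    means = [exposure_block_mean(p.gamma_G, svs[0], ld),
             exposure_block_mean(p.gamma_GI, svs[1], ld),
             outcome_gwas_mean(p, svs[2], svs[3], ld, mod),
             outcome_gwis_mean(p, svs[2], svs[3], ld, mod)]
    want = sum(stats.multivariate_normal.logpdf(o, mean=mu, cov=np.diag(s) @ R @ np.diag(s))
               for o, mu, s in zip(obs, means, svs))
    assert got == pytest.approx(want, rel=1e-10)


def test_loglik_block_subset_and_errors(small_panel):
    panel, truth = small_panel
    p = MerlinParams(truth["beta_A"], truth["beta_I"], truth["gamma_G"],
                     truth["gamma_GI"], truth["beta_G"])
    mod = mm.ModifierSpec.binary(0.5)
    full = log_likelihood(p, panel, None, mod)
    parts = sum(log_likelihood(p, panel, None, mod, blocks=[b]) for b in BLOCKS)
    assert full == pytest.approx(parts)
    with pytest.raises(ValueError):
        log_likelihood(p, panel, None, mod, blocks=["nope"])


# ---------------------------------------------------------------------------
# the moment-structure oracle
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("mod, h2gi", [
    (mm.ModifierSpec.binary(0.5), 0.3),
    (mm.ModifierSpec.binary(0.25), 0.15),
    (mm.ModifierSpec.continuous(), 0.15),
], ids=["binary-balanced", "binary-p0.25", "continuous"])
def test_moment_structure_oracle(mod, h2gi):
    """Engine regression coefficients match the likelihood means at truth.

    One large cohort (n=150,000) per modifier preset; every per-SNP deviation
    between the observed coefficient and the model mean, in units of its SE,
    must look standard normal (no deviation beyond 4.2 SEs among 4 x 36
    checks, and mean deviation near 0).
    """
    sc = mm.SimulationScenario(
        n_exposure=150_000, n_outcome=150_000, m_snps=36,
        h2_gamma_GI=h2gi, rho_AI=0.4 if mod.kind == "binary" else 0.0,
        beta_A=0.1, beta_I=0.3, modifier=mod, seed=20)
    panel, truth = mm.simulate_scenario(sc)
    p = MerlinParams(truth["beta_A"], truth["beta_I"], truth["gamma_G"],
                     truth["gamma_GI"], truth["beta_G"])
    devs = np.concatenate([
        (panel.gamma_G - exposure_block_mean(p.gamma_G, panel.s1, None)) / panel.s1,
        (panel.gamma_GI - exposure_block_mean(p.gamma_GI, panel.s2, None)) / panel.s2,
        (panel.Gamma_G - outcome_gwas_mean(p, panel.s3, panel.s4, None, mod)) / panel.s3,
        (panel.Gamma_GI - outcome_gwis_mean(p, panel.s3, panel.s4, None, mod)) / panel.s4,
    ])
    assert np.abs(devs).max() < 4.2
    assert abs(devs.mean()) < 3.0 / math.sqrt(len(devs))


def test_mu3_term_is_required_at_p025():
    """Dropping the skewness cross-term breaks the outcome-GWIS mean."""
    mod = mm.ModifierSpec.binary(0.25)
    sc = mm.SimulationScenario(
        n_exposure=150_000, n_outcome=150_000, m_snps=36,
        h2_gamma_GI=0.15, beta_A=0.0, beta_I=0.3, modifier=mod, seed=21)
    panel, truth = mm.simulate_scenario(sc)
    p = MerlinParams(0.0, 0.3, truth["gamma_G"], truth["gamma_GI"], truth["beta_G"])
    wrong = (panel.Gamma_GI - p.Gamma_GI) / panel.s4  # mean without the mu3 term
    right = (panel.Gamma_GI
             - outcome_gwis_mean(p, panel.s3, panel.s4, None, mod)) / panel.s4
    assert np.abs(wrong).max() > 6.0
    assert np.abs(right).max() < 4.2
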