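"""Gibbs-sampler estimation: recovery, calibration plumbing, reductions."""

import numpy as np
import pytest

import merlin_mr as mm
from merlin_mr import McmcConfig, fit_merlin, fit_merlin_no_outcome_gwis, wald_p


# ---------------------------------------------------------------------------
# wald_p
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("mean, sd, expected", [
    (0.0, 1.0, 1.0),
    (1.959964, 1.0, 0.05),
    (0.3, 0.1, 0.0026998),
])
def test_wald_p_values(mean, sd, expected):
    assert wald_p(mean, sd) == pytest.approx(expected, rel=1e-4)


def test_wald_p_domain():
    with pytest.raises(ValueError):
        wald_p(0.1, 0.0)


def test_mcmc_config_validation():
    with pytest.raises(ValueError):
        McmcConfig(n_iter=100, n_burnin=100)
    with pytest.raises(ValueError):
        McmcConfig(n_chains=0)


# ---------------------------------------------------------------------------
# recovery and structure
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def recovery_fit():
    sc = mm.SimulationScenario(beta_A=0.3, beta_I=0.0, h2_gamma_GI=0.1,
                               m_snps=200, n_exposure=20_000, n_outcome=20_000,
                               seed=31)
    panel, truth = mm.simulate_scenario(sc)
    fit = fit_merlin(panel, mod=sc.modifier, cfg=McmcConfig(2000, 500, 2, seed=31),
                     error_corr=truth["err_corr_matrix"])
    return fit


def test_average_effect_recovery(recovery_fit):
    fit = recovery_fit
    assert abs(fit.beta_A_mean - 0.3) < 3 * fit.beta_A_sd
    lo, hi = fit.beta_I_ci95
    assert lo < 0.0 < hi
    assert fit.beta_A_ci95[0] < fit.beta_A_mean < fit.beta_A_ci95[1]


def test_convergence_diagnostics(recovery_fit):
    assert set(recovery_fit.rhat) == {"beta_A", "beta_I"}
    assert recovery_fit.converged
    assert recovery_fit.beta_A_sd > 0
    assert set(recovery_fit.sigma2_means) == {"sigma2_1", "sigma2_2", "sigma2_3"}


def test_illustrative_scenario_single_replicate(small_scenario):
    """Sex-inverted truth: the joint fit separates beta_A ~ 0 from beta_I ~ 0.3."""
    panel, truth = mm.simulate_scenario(small_scenario)
    fit = fit_merlin(panel, mod=small_scenario.modifier,
                     cfg=McmcConfig(2000, 500, 1, seed=1),
                     error_corr=truth["err_corr_matrix"])
    assert abs(fit.beta_I_mean - 0.3) < 4 * fit.beta_I_sd
    assert abs(fit.beta_A_mean) < 4 * fit.beta_A_sd
    # the classical sex-combined estimator is badly biased on the same panel
    ivw = mm.ivw(panel.gamma_G, panel.s1, panel.Gamma_G, panel.s3)
    assert ivw.estimate > 0.1 and ivw.p < 1e-6


def test_no_signal_null():
    """With both interaction channels empty, beta_I concentrates near zero."""
    m = 80
    rng = np.random.Generator(np.random.PCG64(5))
    s = np.full(m, 0.01)
    gamma = rng.normal(0, 0.05, m)
    panel = mm.HarmonizedPanel.from_arrays(
        [f"rs{i}" for i in range(m)],
        gamma + rng.normal(0, 0.01, m), s,
        np.zeros(m), np.full(m, 10.0),            # gwis channel: no information
        0.2 * gamma + rng.normal(0, 0.01, m), s,
        np.zeros(m) + rng.normal(0, 0.01, m), s)  # outcome gwis pure noise
    fit = fit_merlin(panel, cfg=McmcConfig(2000, 500, 1, seed=2))
    assert abs(fit.beta_I_mean) < 3 * fit.beta_I_sd
    assert abs(fit.beta_A_mean - 0.2) < 3 * fit.beta_A_sd


def test_seed_reproducibility(small_panel, small_scenario):
    panel, _ = small_panel
    cfg = McmcConfig(600, 200, 2, seed=9)
    f1 = fit_merlin(panel, mod=small_scenario.modifier, cfg=cfg)
    f2 = fit_merlin(panel, mod=small_scenario.modifier, cfg=cfg)
    np.testing.assert_array_equal(f1.chains["beta_A"], f2.chains["beta_A"])
    np.testing.assert_array_equal(f1.chains["beta_I"], f2.chains["beta_I"])
    f3 = fit_merlin(panel, mod=small_scenario.modifier,
                    cfg=McmcConfig(600, 200, 2, seed=10))
    assert not np.array_equal(f1.chains["beta_A"], f3.chains["beta_A"])


def test_sign_symmetry_under_modifier_negation(small_panel, small_scenario):
    """Swapping strata negates beta_I and leaves beta_A unchanged."""
    panel, _ = small_panel
    cfg = McmcConfig(1500, 500, 1, seed=3)
    fit = fit_merlin(panel, mod=small_scenario.modifier, cfg=cfg)
    flipped = mm.HarmonizedPanel.from_arrays(
        panel.snp_ids, panel.gamma_G, panel.s1, -panel.gamma_GI, panel.s2,
        panel.Gamma_G, panel.s3, -panel.Gamma_GI, panel.s4)
    fit2 = fit_merlin(flipped, mod=small_scenario.modifier, cfg=cfg)
    tol = 3 * np.hypot(fit.beta_I_sd, fit2.beta_I_sd)
    assert abs(fit.beta_I_mean + fit2.beta_I_mean) < tol
    assert abs(fit.beta_A_mean - fit2.beta_A_mean) < tol


def test_reduction_to_ivw():
    """beta_I pinned at 0 + uninformative GWIS blocks ~ classical IVW."""
    rng = np.random.Generator(np.random.PCG64(17))
    m = 150
    gamma = rng.normal(0, 0.06, m)
    s1 = np.full(m, 0.004)
    s3 = np.full(m, 0.01)
    z1 = gamma + rng.normal(0, 1, m) * s1
    z3 = 0.3 * gamma + rng.normal(0, 1, m) * s3
    big = np.full(m, 100.0)
    panel = mm.HarmonizedPanel.from_arrays(
        [f"rs{i}" for i in range(m)], z1, s1, np.zeros(m), big, z3, s3,
        np.zeros(m), big)
    fit = fit_merlin(panel, cfg=McmcConfig(2500, 500, 1, seed=4), fix_beta_I=True)
    ivw = mm.ivw(z1, s1, z3, s3)
    assert fit.beta_I_mean == 0.0 and fit.beta_I_sd == 0.0
    assert abs(fit.beta_A_mean - ivw.estimate) < 2 * np.hypot(fit.beta_A_sd, ivw.se)


def test_dense_ld_path_agrees_with_identity(small_panel, small_scenario):
    """A near-identity dense R reproduces the independent-instrument fit."""
    panel, _ = small_panel
    m = len(panel)
    R = np.eye(m)
    R[0, 1] = R[1, 0] = 1e-3
    fit_d = fit_merlin(panel, R=mm.LDMatrix(panel.snp_ids, R),
                       mod=small_scenario.modifier, cfg=McmcConfig(1200, 400, 1, seed=6))
    fit_i = fit_merlin(panel, mod=small_scenario.modifier,
                       cfg=McmcConfig(1200, 400, 1, seed=6))
    assert abs(fit_d.beta_A_mean - fit_i.beta_A_mean) < 3 * np.hypot(fit_d.beta_A_sd, fit_i.beta_A_sd)
    assert abs(fit_d.beta_I_mean - fit_i.beta_I_mean) < 3 * np.hypot(fit_d.beta_I_sd, fit_i.beta_I_sd)


def test_error_corr_argument_forms(small_panel, small_scenario):
    panel, truth = small_panel
    cfg = McmcConfig(400, 100, 1, seed=8)
    for ec in ("zero", "estimate", (0.4, 0.2), truth["err_corr_matrix"]):
        fit = fit_merlin(panel, mod=small_scenario.modifier, cfg=cfg, error_corr=ec)
        assert np.isfinite(fit.beta_I_mean)
    with pytest.raises(ValueError):
        fit_merlin(panel, mod=small_scenario.modifier, cfg=cfg, error_corr="bogus")


def test_degenerate_panel_warns():
    m = 10
    s = np.full(m, 0.01)
    panel = mm.HarmonizedPanel.from_arrays(
        [f"rs{i}" for i in range(m)], np.zeros(m), s, np.zeros(m), s,
        np.zeros(m), s, np.zeros(m), s)
    with pytest.warns(RuntimeWarning, match="degenerate"):
        fit_merlin(panel, cfg=McmcConfig(200, 50, 1, seed=0))
    with pytest.raises(ValueError):
        fit_merlin(panel.subset(panel.snp_ids[:1]), cfg=McmcConfig(200, 50, 1))


# ---------------------------------------------------------------------------
# reduced-data mode (no outcome GWIS)
# ---------------------------------------------------------------------------

def test_no_outcome_gwis_recovery(small_scenario):
    panel, truth = mm.simulate_scenario(small_scenario)
    cfg = McmcConfig(2000, 500, 1, seed=11)
    full = fit_merlin(panel, mod=small_scenario.modifier, cfg=cfg)
    red = fit_merlin_no_outcome_gwis(panel, mod=small_scenario.modifier, cfg=cfg)
    assert red.experimental
    assert abs(red.beta_I_mean - 0.3) < 4 * red.beta_I_sd
    assert red.beta_I_sd > full.beta_I_sd  # less information without the block


def test_no_outcome_gwis_unidentified_warns():
    """Without exposure interaction signal, beta_I has no leakage channel."""
    rng = np.random.Generator(np.random.PCG64(13))
    m = 60
    gamma = rng.normal(0, 0.05, m)
    s = np.full(m, 0.01)
    panel = mm.HarmonizedPanel.from_arrays(
        [f"rs{i}" for i in range(m)],
        gamma + rng.normal(0, 0.01, m), s,
        rng.normal(0, 0.01, m), s,                  # gamma_GI truth = 0
        0.1 * gamma + rng.normal(0, 0.01, m), s,
        rng.normal(0, 0.01, m), s)
    fit = fit_merlin_no_outcome_gwis(panel, cfg=McmcConfig(1500, 500, 1, seed=12))
    assert fit.beta_I_sd > 0.5
    assert any("weakly identified" in w for w in fit.warnings)


def test_no_outcome_gwis_beta_A_agrees_on_null_interaction():
    sc = mm.SimulationScenario(beta_A=0.25, beta_I=0.0, h2_gamma_GI=0.15,
                               m_snps=100, n_exposure=10_000, n_outcome=10_000,
                               seed=14)
    panel, truth = mm.simulate_scenario(sc)
    cfg = McmcConfig(1500, 500, 1, seed=14)
    full = fit_merlin(panel, mod=sc.modifier, cfg=cfg)
    red = fit_merlin_no_outcome_gwis(panel, mod=sc.modifier, cfg=cfg)
    assert abs(full.beta_A_mean - red.beta_A_mean) < 3 * np.hypot(full.beta_A_sd, red.beta_A_sd)


def test_fit_json_roundtrip(tmp_path, recovery_fit):
    recovery_fit.to_json(tmp_path / "fit.json")
    import json
    d = json.loads((tmp_path / "fit.json").read_text())
    assert d["beta_A"]["mean"] == recovery_fit.beta_A_mean
    assert d["n_snps"] == 200
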