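import numpy as np
import pytest
from hypothesis import settings

import merlin_mr as mm

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_scenario() -> mm.SimulationScenario:
    """Desk-size sex-inverted scenario: quick but with real signal."""
    return mm.SimulationScenario.illustrative(
        seed=7, m_snps=60, n_exposure=6000, n_outcome=6000)


@pytest.fixture(scope="session")
def small_panel(small_scenario):
    panel, truth = mm.simulate_scenario(small_scenario)
    return panel, truth


@pytest.fixture()
def rng():
    return np.random.Generator(np.random.PCG64(12345))


def make_table(snp_ids, beta, se, *, ea=None, oa=None, maf=None, n=None, p=None,
               pos=None, kind="GWAS"):
    """Hand-built sumstats table with explicit per-row alleles."""
    import pandas as pd
    m = len(snp_ids)
    df = pd.DataFrame({
        "snp": snp_ids,
        "chrom": "1",
        "pos": pos if pos is not None else np.arange(1, m + 1) * 10_000,
        "ea": ea if ea is not None else ["A"] * m,
        "oa": oa if oa is not None else ["G"] * m,
        "maf": maf if maf is not None else [0.3] * m,
        "beta": beta,
        "se": se,
        "n": n if n is not None else [10_000.0] * m,
    })
    if p is not None:
        df["p"] = p
    return mm.SumstatsTable(df, analysis_kind=kind)
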