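"""Shared fixtures: one default synthetic study and one fitted LNP pipeline.

Session-scoped so the expensive pieces (DE on the default matrix, the
forest fit, the GA run) execute once for the whole suite.
"""

from __future__ import annotations

import pandas as pd
import pytest

import nanovax as nv


@pytest.fixture(scope="session")
def default_matrix() -> nv.ExpressionMatrix:
    cfg = nv.SimConfig(seed=0)
    return nv.simulate_expression(nv.build_gene_catalog(cfg), cfg)


@pytest.fixture(scope="session")
def default_de(default_matrix) -> pd.DataFrame:
    return nv.wald_test(default_matrix)


@pytest.fixture(scope="session")
def lnp_dataset() -> nv.LNPDataset:
    return nv.sample_formulations(n=100, seed=0, noise_sd=0.1)


@pytest.fixture(scope="session")
def fitted_surrogate(lnp_dataset):
    train, valid = nv.split_dataset(lnp_dataset, seed=0)
    model = nv.train_rf(train, seed=0)
    return model, train, valid


@pytest.fixture(scope="session")
def ga_result(fitted_surrogate) -> nv.GAResult:
    model, _, _ = fitted_surrogate
    return nv.run_ga(model, nv.GAConfig(seed=0))
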