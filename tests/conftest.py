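"""Shared fixtures: small models and synthetic study data, session-scoped so
expensive training runs are shared between tests."""

from __future__ import annotations

import numpy as np
import pytest

from submdta import (DtaConfig, FixtureSpec, PretrainConfig,
                     generate_fixture_molecules, generate_synthetic_dta,
                     pretrain, split_records)

# desk-scale widths used across the suite (full-size defaults are exercised
# only for shape contracts, never trained in tests)
SMALL_HIDDEN = 32
SMALL_PROTEIN = dict(embed_dim=32, protein_hidden=16)


@pytest.fixture(scope="session")
def fixture_molecules() -> list[str]:
    return generate_fixture_molecules(200, seed=1)


@pytest.fixture(scope="session")
def synthetic_study():
    """The synthetic DTA study: 200 drugs x 20 proteins, noise_sd 0.3."""
    spec = FixtureSpec(n_molecules=200, n_proteins=20, seed=0, noise_sd=0.3)
    records, truth = generate_synthetic_dta(spec)
    return spec, records, truth


@pytest.fixture(scope="session")
def synthetic_split(synthetic_study):
    _, records, _ = synthetic_study
    return split_records(records, test_fraction=0.2, seed=0)


@pytest.fixture(scope="session")
def pretrained_small():
    """Encoder pre-trained 20 epochs on 200 fixture molecules (seed 0)."""
    mols = generate_fixture_molecules(200, seed=0)
    config = PretrainConfig(hidden_dim=SMALL_HIDDEN, n_layers=4, T=1,
                            batch_size=32, epochs=20, seed=0)
    model, history = pretrain(mols, config)
    return model, history


@pytest.fixture()
def small_dta_config() -> DtaConfig:
    return DtaConfig(hidden_dim=SMALL_HIDDEN, n_layers=4, head_dims=(128, 64),
                     batch_size=128, seed=0, **SMALL_PROTEIN)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
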