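"""Shared fixtures: small seeded synthetic datasets built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from cordatlas import qc, synthetic as syn


@pytest.fixture(scope="session")
def small_hierarchy():
    return syn.build_hierarchy(
        n_coarse=2, n_fine_per_coarse=3, markers_per_type=8,
        overlap_fraction=0.0, seed=42, n_genes=400,
    )


@pytest.fixture(scope="session")
def small_config():
    return syn.SimulationConfig(
        seed=42, n_genes=400, doublet_rate=0.05, lowq_rate=0.05,
        batch_effect_strength=0.5,
    )


@pytest.fixture(scope="session")
def small_study(small_hierarchy, small_config):
    profile = syn.StudyProfile("unit", protocol="nucleus", n_cells=400)
    return syn.simulate_study(small_hierarchy, profile, small_config)


@pytest.fixture(scope="session")
def small_norm(small_study):
    adata, _ = small_study
    filtered, _ = qc.qc_filter(adata)
    return qc.log_normalize(filtered)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
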