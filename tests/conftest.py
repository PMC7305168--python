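"""Shared fixtures: one default-scale simulated study per session, plus a
reduced-scale annotation for cheap structural tests."""

from __future__ import annotations

import pytest

from methtx import methylome, simulate


@pytest.fixture(scope="session")
def default_config() -> simulate.SimConfig:
    return simulate.SimConfig(seed=0)


@pytest.fixture(scope="session")
def default_annotation(default_config):
    return simulate.simulate_annotation(default_config)


@pytest.fixture(scope="session")
def default_methylomes(default_config, default_annotation):
    return simulate.simulate_methylome(default_config, default_annotation)


@pytest.fixture(scope="session")
def pooled_calls(default_config, default_methylomes):
    """Replicate-pooled call table per genotype."""
    out = {}
    for genotype in ("WT", "Dnmt1KO", "DKO", "ICM"):
        tables = [
            t for (g, _), t in default_methylomes.items() if g == genotype
        ]
        out[genotype] = methylome.pool_replicates(tables)
    return out


@pytest.fixture(scope="session")
def default_counts(default_config, default_annotation):
    return simulate.simulate_counts(default_config, default_annotation)


@pytest.fixture(scope="session")
def small_annotation():
    return simulate.simulate_annotation(simulate.small_config(3))
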