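import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from vigornet.config import SimConfig  # noqa: E402


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A fast desk-scale world: 40 samples, 120 genes, 8 regulators."""
    return SimConfig(
        n_samples=40,
        n_genes=120,
        n_factors=8,
        targets_per_factor=4,
        ppi_edges=80,
        n_mirna_targets=6,
        planted_category_counts={c: 5 for c in range(1, 9)},
        seed=7,
    )


@pytest.fixture(scope="session")
def noiseless_cfg() -> SimConfig:
    """Deterministic planted structure: no target noise, unit effects."""
    return SimConfig(
        n_samples=40,
        n_genes=80,
        n_factors=5,
        targets_per_factor=4,
        effect_size=1.0,
        noise_sd=0.0,
        ppi_edges=40,
        n_mirna_targets=4,
        seed=11,
    )
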