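import numpy as np
import pytest

from rcaspot.panel import GenePanel
from rcaspot.simulate import SimConfig, default_airway_types, simulate_field


def airway_panel(genes):
    """Pack genes into cycles of 3 signal channels (channel 0 = DAPI)."""
    return GenePanel({g: (i // 3, 1 + i % 3) for i, g in enumerate(genes)})


def small_sim_config(seed=0, **overrides):
    """A fast, sparse field used across the detection/counting tests."""
    types = default_airway_types(selective_rate=2.0, background_rate=0.1)
    genes = sorted({g for t in types for g in t.rates})
    panel = airway_panel(genes)
    kwargs = dict(
        field_size_px=(384, 384),
        n_cells=25,
        cell_types=types,
        panel=panel,
        cycle_shifts_px=[(0, 0)] * panel.n_cycles,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def small_field():
    """One simulated field shared by read-only tests."""
    cfg = small_sim_config(seed=7)
    truth, stack = simulate_field(cfg)
    return cfg, truth, stack


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
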