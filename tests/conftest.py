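import numpy as np
import pytest

from dlgrowth import lattice
from dlgrowth.indices import mean_index_over_realisations


@pytest.fixture(scope="session")
def scenario_ensembles():
    """Mean index per scenario over 20 independently seeded 200x200 runs.

    These are the standard study conditions (s = 3, c0 = 1) grown to the
    conventional stopping density for each scenario; computed once per
    session because several tests assert on different aspects of them.
    """
    out = {}
    specs = {
        "theta": ("uniform_single", 0.2),
        "c": ("uniform_two_seeds", 0.2),
        "b": ("nutrient_column", 0.1),
    }
    for kind, (scenario, stop) in specs.items():
        cfg = lattice.LatticeConfig(
            L_x=200, L_y=200, s=3, c0=1.0, scenario=scenario, stop_density=stop
        )
        out[kind] = mean_index_over_realisations(cfg, 20, kind, base_seed=1000)
    return out


@pytest.fixture(scope="session")
def small_run():
    """One small, fast converged simulation shared by plumbing tests."""
    cfg = lattice.LatticeConfig(
        L_x=60, L_y=60, s=3, c0=1.0, scenario="uniform_single",
        stop_density=0.2, rng_seed=5,
    )
    return lattice.run_until_density(cfg)
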