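import numpy as np
import pytest
from hypothesis import settings

import privgood as pg

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def interior_params():
    """Constants with a unique interior coexistence fraction (~0.397)."""
    return pg.ModelParams(fmax=1.0, Km=1.0, C=0.1, r=1.0, alpha=0.2)


@pytest.fixture
def regime():
    """The study's serial-transfer design: 1:100 daily, ~200 generations."""
    return pg.TransferRegime(dilution_factor=100.0, n_transfers=30,
                             assay_interval_generations=50.0)


def grid_scan_root(params, step=1e-6):
    """Independent oracle: locate the sign change of the fitness gap on a
    uniform x-grid and return the bracket midpoint."""
    x = np.linspace(0.0, 1.0, int(round(1.0 / step)) + 1)
    g = pg.fitness_gap(params, x)
    sign = np.sign(g)
    flips = np.flatnonzero(sign[:-1] != sign[1:])
    if flips.size == 0:
        return None
    i = flips[0]
    return 0.5 * (x[i] + x[i + 1])


def random_interior_params(rng):
    """Random valid constants conditioned on an interior coexistence root."""
    while True:
        p = pg.ModelParams(
            fmax=float(rng.uniform(0.2, 3.0)),
            Km=float(rng.uniform(0.05, 3.0)),
            C=float(rng.uniform(0.005, 0.5)),
            r=float(rng.uniform(0.05, 5.0)),
            alpha=float(rng.uniform(0.01, 0.99)),
        )
        if pg.fitness_gap(p, 0.0) > 0.0 > pg.fitness_gap(p, 1.0):
            return p
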