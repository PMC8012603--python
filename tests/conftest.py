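import numpy as np
import pytest

from pcfret import PairSimSpec, power_law_pair_model

# study conditions of the validation: photochromic donor rho0 = 0.3,
# photostatic partner rho0 = 1.0, efficiencies in [0, 0.6]
THETA_RANGE = (0.0, 0.6)


@pytest.fixture
def sim_specs():
    return (PairSimSpec(brightness_n=4000.0, rho0=0.3),
            PairSimSpec(brightness_n=4000.0, rho0=1.0))


@pytest.fixture
def pair_models(sim_specs):
    return (power_law_pair_model("photochromic", sim_specs[0], THETA_RANGE),
            power_law_pair_model("photostatic", sim_specs[1], THETA_RANGE))


def forward_oracle_grid(on, off, specs, grid):
    """Independent brute-force inversion: exhaustive residual minimization.

    Evaluates the forward model on every (theta1, theta2) candidate in
    ``grid`` x ``grid`` and returns the pair minimizing the squared
    residual against the observed four signals.  Kept free of the
    iterative solver on purpose.
    """
    g = np.asarray(grid, dtype=float)
    t1 = g[:, None]
    t2 = g[None, :]
    n1, n2 = specs[0].brightness_n, specs[1].brightness_n
    g1, g2 = specs[0].gamma, specs[1].gamma
    r1 = specs[0].rho0 ** (1.0 - t1)
    r2 = specs[1].rho0 ** (1.0 - t2)
    dd_on = n1 * (1 - t1) + n2 * (1 - t2)
    da_on = g1 * n1 * t1 + g2 * n2 * t2
    dd_off = r1 * n1 * (1 - t1) + r2 * n2 * (1 - t2)
    da_off = r1 * g1 * n1 * t1 + r2 * g2 * n2 * t2
    resid = (
        (dd_on - on.s_dd) ** 2 + (da_on - on.s_da) ** 2
        + (dd_off - off.s_dd) ** 2 + (da_off - off.s_da) ** 2
    )
    i, j = np.unravel_index(np.argmin(resid), resid.shape)
    return float(g[i]), float(g[j])
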