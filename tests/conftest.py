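import numpy as np
import pytest

from seedgca import synthetic


TINY_LAYOUT = {
    "seed_l": ((0, 2), (0, 2), (0, 2)),
    "seed_r": ((4, 6), (0, 2), (0, 2)),
    "itg": ((0, 2), (4, 6), (0, 2)),
    "visual": ((4, 6), (4, 6), (0, 2)),
    "wm": ((6, 8), (6, 8), (2, 4)),
    "csf": ((0, 2), (6, 8), (2, 4)),
}


def tiny_cohort_config(**overrides) -> synthetic.CohortConfig:
    """A miniature cohort configuration for fast unit tests."""
    defaults = dict(
        n_group_a=3,
        n_group_b=3,
        grid_dims=(8, 8, 4),
        n_volumes=125,
        region_layout=dict(TINY_LAYOUT),
        rng_seed=7,
    )
    defaults.update(overrides)
    return synthetic.default_cohort_config(**defaults)


@pytest.fixture(scope="session")
def tiny_cohort() -> synthetic.Cohort:
    return synthetic.synthesize_cohort(tiny_cohort_config())


def ar1_pair(t_len: int, coupling: float, rng, a_x: float = 0.5, a_y: float = 0.5):
    """Directly iterated pair: x is autonomous AR(1), y receives x's lag."""
    burn = 200
    x = np.zeros(t_len + burn)
    y = np.zeros(t_len + burn)
    ex = rng.standard_normal(t_len + burn)
    ey = rng.standard_normal(t_len + burn)
    for t in range(1, t_len + burn):
        x[t] = a_x * x[t - 1] + ex[t]
        y[t] = a_y * y[t - 1] + coupling * x[t - 1] + ey[t]
    return x[burn:], y[burn:]
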