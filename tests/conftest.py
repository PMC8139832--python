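import numpy as np
import pytest

from morphodyn.reaction_diffusion import (KineticParams, SpatialGrid,
                                          TwoStateModel, build_binding_profile)


@pytest.fixture(scope="session")
def small_grid():
    return SpatialGrid(L=50.0, dx=0.1)


@pytest.fixture(scope="session")
def periodic_binding(small_grid):
    return build_binding_profile(
        small_grid, {"kind": "periodic", "a_max": 10.0, "p1": 2.0, "p2": 0.2})


@pytest.fixture(scope="session")
def small_steady(small_grid, periodic_binding):
    """Near-steady two-state run on a 50 µm domain (shared across tests).

    The short closed domain needs ~200 s for the tail at the reflecting
    far boundary to settle.
    """
    kin = KineticParams(D=20.0, b=0.1, c=0.1, g_max=0.2, R=1.0, dt=2e-4)
    model = TwoStateModel(small_grid, kin, periodic_binding)
    result = model.simulate(t_end=200.0, record_every=100.0)
    return model, result


def naive_multitau(trace, dt, m=16):
    """Brute-force reference correlator: the estimator written straight from
    its definition (mean of lagged products over symmetric window means),
    with explicit block-averaging per octave.  Independent of the streaming
    multi-tau implementation; O(N^2) total work.
    """
    y = np.asarray(trace, dtype=float)
    taus, gs = [], []
    for k in range(1, 2 * m + 1):
        num = np.mean(y[:-k] * y[k:])
        gs.append(num / (np.mean(y[:-k]) * np.mean(y[k:])))
        taus.append(k * dt)
    level = 1
    cur = y
    while True:
        cur = cur[:2 * (cur.size // 2)]
        cur = cur.reshape(-1, 2).mean(axis=1)
        if cur.size < 2 * m + 1:
            break
        for k in range(m + 1, 2 * m + 1):
            num = np.mean(cur[:-k] * cur[k:])
            gs.append(num / (np.mean(cur[:-k]) * np.mean(cur[k:])))
            taus.append(k * dt * 2 ** level)
        level += 1
    return np.array(taus), np.array(gs)


def reduced_reference_run(b: float, c: float, L: float = 400.0):
    """Half-resolution reference-scenario run for fast checks.

    dx = 0.2, dt = 4e-4 keeps the stability number at 0.2 and changes the
    fitted decay length by well under 1%.
    """
    grid = SpatialGrid(L=L, dx=0.2)
    kin = KineticParams(D=20.0, b=b, c=c, g_max=0.2, R=1.0, dt=4e-4)
    binding = build_binding_profile(
        grid, {"kind": "periodic", "a_max": 10.0, "p1": 2.0, "p2": 0.2})
    model = TwoStateModel(grid, kin, binding)
    result = model.simulate(t_end=100.0, record_every=100.0)
    return grid, kin, binding, result
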