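"""Unit and property tests for the two-state reaction-diffusion core."""

import numpy as np
import pytest

from morphodyn.reaction_diffusion import (KineticParams, LigandState,
                                          SimulationResult, SourceProfile,
                                          SpatialGrid, TwoStateModel,
                                          build_binding_profile,
                                          build_source_profile,
                                          check_steady_state, step_forward,
                                          total_mass)

from conftest import reduced_reference_run


# ---------------------------------------------------------------- grid/params

def test_grid_node_layout():
    grid = SpatialGrid(L=1000.0, dx=0.1)
    assert grid.n_points == 10001
    assert grid.x[0] == 0.0
    assert grid.x[-1] == pytest.approx(1000.0)


@pytest.mark.parametrize("kwargs", [dict(L=0, dx=0.1), dict(L=10, dx=-1)])
def test_grid_rejects_bad_dimensions(kwargs):
    with pytest.raises(ValueError):
        SpatialGrid(**kwargs)


def test_stability_guard_names_the_number():
    grid = SpatialGrid(L=10.0, dx=0.1)
    kin = KineticParams(D=20.0, dt=1e-3)  # D*dt/dx^2 = 2
    with pytest.raises(ValueError, match="D\\*dt/dx\\^2"):
        kin.check_stability(grid)


# ---------------------------------------------------------------- binding

def test_periodic_sites_cover_width_p2(small_grid, periodic_binding):
    a, x = periodic_binding.a, small_grid.x
    # site 1 occupies [2, 2.2): nodes 2.0 and 2.1, not 2.2
    assert a[x == 2.0] == 10.0 and a[np.isclose(x, 2.1)] == 10.0
    assert a[np.isclose(x, 2.2)] == 0.0
    assert a[np.isclose(x, 3.0)] == 0.0
    # mean binding rate matches a_max * p2 / p1
    assert small_grid.dx * a.sum() / small_grid.L == pytest.approx(1.0, rel=0.05)


def test_band_scenario_masks_sites_outside_window():
    grid = SpatialGrid(L=100.0, dx=0.1)
    b = build_binding_profile(grid, {"kind": "band", "a_max": 10.0,
                                     "p1": 2.0, "p2": 0.2, "band": (50, 60)})
    nz = grid.x[b.a > 0]
    assert nz.min() >= 50.0 and nz.max() <= 60.0
    assert (b.a[(grid.x >= 50) & (grid.x <= 60)] > 0).any()


def test_absent_beyond_scenario_stops_at_cutoff():
    grid = SpatialGrid(L=100.0, dx=0.1)
    b = build_binding_profile(grid, {"kind": "absent_beyond", "a_max": 10.0,
                                     "p1": 2.0, "p2": 0.2, "cutoff": 10.0})
    assert (grid.x[b.a > 0] <= 10.0).all()
    assert b.a.max() == 10.0


def test_zero_scenario_is_empty():
    grid = SpatialGrid(L=10.0, dx=0.1)
    b = build_binding_profile(grid, {"kind": "periodic", "a_max": 0.0})
    assert b.scenario == "zero" and not b.a.any() and b.n_sites() == 0


def test_random_halfnormal_reproducible_and_scaled():
    grid = SpatialGrid(L=1000.0, dx=0.1)
    spec = {"kind": "random_halfnormal", "a_max": 10.0, "p1": 2.0, "p2": 0.2}
    b1 = build_binding_profile(grid, spec, seed=7)
    b2 = build_binding_profile(grid, spec, seed=7)
    b3 = build_binding_profile(grid, spec, seed=8)
    assert np.array_equal(b1.a, b2.a)
    assert not np.array_equal(b1.a, b3.a)
    amps = np.array([b1.a[(grid.x >= lo) & (grid.x < hi)].max()
                     for lo, hi in b1.site_intervals])
    # half-normal with mean a_max = 10
    assert amps.mean() == pytest.approx(10.0, rel=0.15)
    assert (amps >= 0).all()


@pytest.mark.parametrize("spec", [
    {"kind": "periodic", "a_max": 10.0, "p1": 1.0, "p2": 1.5},  # overlap
    {"kind": "band", "a_max": 10.0, "band": (90, 120)},         # outside
    {"kind": "nonsense", "a_max": 1.0},
    {"kind": "random_halfnormal", "a_max": 10.0},               # no seed
])
def test_bad_scenarios_rejected(spec):
    grid = SpatialGrid(L=100.0, dx=0.1)
    with pytest.raises(ValueError):
        build_binding_profile(grid, spec)


# ---------------------------------------------------------------- stepping

def _tiny_problem(seed=0):
    grid = SpatialGrid(L=1.0, dx=0.1)  # 11 nodes
    kin = KineticParams(D=2.0, b=0.3, c=0.2, g_max=0.5, R=0.3, dt=1e-3)
    rng = np.random.default_rng(seed)
    a = rng.random(grid.n_points)
    g = build_source_profile(grid, kin).g
    state = LigandState(u=rng.random(grid.n_points), v=rng.random(grid.n_points))
    from morphodyn.reaction_diffusion import BindingProfile
    binding = BindingProfile(a=a, scenario="periodic", a_max=1.0)
    return grid, kin, binding, SourceProfile(g=g), state


def test_step_matches_hand_coded_stencil():
    """One explicit step equals a node-by-node evaluation of the scheme."""
    grid, kin, binding, source, state = _tiny_problem()
    new = step_forward(state, grid, kin, binding, source)

    u, v, a, g = state.u, state.v, binding.a, source.g
    dt, dx, D, b, c = kin.dt, grid.dx, kin.D, kin.b, kin.c
    n = grid.n_points
    for i in range(n):
        left = u[1] if i == 0 else u[i - 1]
        right = u[n - 2] if i == n - 1 else u[i + 1]
        lap = (right - 2 * u[i] + left) / dx**2
        exp_u = u[i] + dt * (D * lap - a[i] * u[i] + b * v[i] + g[i])
        exp_v = v[i] + dt * (a[i] * u[i] - b * v[i] - c * v[i])
        assert new.u[i] == pytest.approx(exp_u, abs=1e-14)
        assert new.v[i] == pytest.approx(exp_v, abs=1e-14)


def test_compiled_kernel_matches_numpy_step():
    grid, kin, binding, source, state = _tiny_problem(seed=3)
    model = TwoStateModel(grid, kin, binding, source)
    res = model.simulate(t_end=10 * kin.dt, record_every=kin.dt,
                         initial=state)
    ref = state
    for _ in range(10):
        ref = step_forward(ref, grid, kin, binding, source)
    np.testing.assert_allclose(res.final.u, ref.u, rtol=0, atol=1e-13)
    np.testing.assert_allclose(res.final.v, ref.v, rtol=0, atol=1e-13)


def test_zero_state_is_fixed_point():
    grid, kin, binding, _, _ = _tiny_problem()
    source = SourceProfile(g=np.zeros(grid.n_points))
    state = LigandState(u=np.zeros(grid.n_points), v=np.zeros(grid.n_points))
    new = step_forward(state, grid, kin, binding, source)
    assert not new.u.any() and not new.v.any()


def test_constant_field_unchanged_without_reactions():
    grid = SpatialGrid(L=1.0, dx=0.1)
    kin = KineticParams(D=2.0, b=0.0, c=0.0, g_max=0.0, R=0.3, dt=1e-3)
    from morphodyn.reaction_diffusion import BindingProfile
    binding = BindingProfile(a=np.zeros(grid.n_points), scenario="zero", a_max=0.0)
    source = SourceProfile(g=np.zeros(grid.n_points))
    state = LigandState(u=np.full(grid.n_points, 3.7), v=np.zeros(grid.n_points))
    new = step_forward(state, grid, kin, binding, source)
    np.testing.assert_allclose(new.u, 3.7, rtol=0, atol=1e-15)


# ---------------------------------------------------------------- simulation

def test_mass_conserved_without_production_or_internalization(small_grid,
                                                              periodic_binding):
    kin = KineticParams(D=20.0, b=0.1, c=0.0, g_max=0.0, R=1.0, dt=2e-4)
    rng = np.random.default_rng(1)
    init = LigandState(u=rng.random(small_grid.n_points),
                       v=rng.random(small_grid.n_points))
    model = TwoStateModel(small_grid, kin, periodic_binding,
                          SourceProfile(g=np.zeros(small_grid.n_points)))
    res = model.simulate(t_end=10.0, record_every=1.0, initial=init)
    masses = [sum(total_mass(s, small_grid)) for s in res.snapshots]
    drift = abs(masses[-1] - masses[0]) / masses[0]
    assert drift < 1e-6  # relative over 10 simulated seconds


def test_fields_stay_nonnegative(small_steady):
    _, result = small_steady
    for snap in result.snapshots:
        assert (snap.u >= 0).all() and (snap.v >= 0).all()


def test_bound_component_peaks_at_sites(small_steady, small_grid,
                                        periodic_binding):
    _, result = small_steady
    v = result.final.v
    on_sites = v[periodic_binding.a > 0]
    off_sites = v[periodic_binding.a == 0]
    assert on_sites.min() > off_sites.max()


def test_step_halving_converges(small_grid, periodic_binding):
    kin1 = KineticParams(D=20.0, b=0.1, c=0.1, g_max=0.2, R=1.0, dt=2e-4)
    kin2 = KineticParams(D=20.0, b=0.1, c=0.1, g_max=0.2, R=1.0, dt=1e-4)
    r1 = TwoStateModel(small_grid, kin1, periodic_binding).simulate(t_end=5.0)
    r2 = TwoStateModel(small_grid, kin2, periodic_binding).simulate(t_end=5.0)
    scale = r1.final.v.max()
    assert np.abs(r1.final.v - r2.final.v).max() / scale < 1e-3
    assert np.abs(r1.final.u - r2.final.u).max() / scale < 1e-3


def test_flux_balance_at_steady_state():
    """Production g_max*R balances total internalization c*integral(v)."""
    grid = SpatialGrid(L=300.0, dx=0.1)
    kin = KineticParams(D=20.0, b=0.1, c=0.1, g_max=0.2, R=1.0, dt=1e-4)
    binding = build_binding_profile(
        grid, {"kind": "periodic", "a_max": 10.0, "p1": 2.0, "p2": 0.2})
    result = TwoStateModel(grid, kin, binding).simulate(t_end=100.0,
                                                        record_every=10.0)
    steady, _ = check_steady_state(result, window=10.0, tol=1e-2)
    assert steady
    internalized = np.trapezoid(kin.c * result.final.v, grid.x)
    assert internalized == pytest.approx(kin.g_max * kin.R, rel=0.02)


def test_steady_state_detector(small_steady):
    model, result = small_steady
    steady, change = check_steady_state(result, window=100.0, tol=1e-2)
    assert steady and change >= 0
    # identical snapshots -> exactly steady
    twin = SimulationResult([result.final.copy(), result.final.copy()],
                            result.grid, result.kin, result.stability_number)
    steady, change = check_steady_state(twin, window=1.0, tol=1e-12)
    assert steady and change == 0.0
    with pytest.raises(ValueError):
        check_steady_state(SimulationResult([], result.grid, result.kin, 0.0),
                           window=1.0)


def test_total_mass_of_unit_field():
    grid = SpatialGrid(L=1000.0, dx=0.5)
    state = LigandState(u=np.ones(grid.n_points), v=np.zeros(grid.n_points))
    mu, mv = total_mass(state, grid)
    assert mu == pytest.approx(1000.0)
    assert mv == 0.0


# ---------------------------------------------------------------- photoconversion

@pytest.fixture(scope="module")
def photoconversion_run(small_steady):
    model, result = small_steady
    return model.simulate_photoconversion(result.final, (10.0, 12.0),
                                          t_end=5.0, record_every=1.0)


def test_labelled_fields_bounded_by_totals(photoconversion_run):
    for s in photoconversion_run.snapshots:
        assert (s.u_lab >= -1e-12).all() and (s.v_lab >= -1e-12).all()
        assert (s.u_lab <= s.u_tot + 1e-9).all()
        assert (s.v_lab <= s.v_tot + 1e-9).all()


def test_labelled_mass_strictly_decreases_with_internalization(
        photoconversion_run, small_grid):
    masses = [np.trapezoid(s.u_lab + s.v_lab, small_grid.x)
              for s in photoconversion_run.snapshots]
    assert all(m2 < m1 for m1, m2 in zip(masses[:-1], masses[1:]))


def test_labelled_signal_spreads_laterally(photoconversion_run, small_grid):
    """Photoconverted molecules disperse into neighbouring regions."""
    first, last = photoconversion_run.snapshots[0], photoconversion_run.snapshots[-1]
    outside = (small_grid.x < 10.0) | (small_grid.x > 12.0)
    assert first.v_lab[outside].max() == 0.0
    assert last.v_lab[outside].max() > 0.0


def test_label_in_empty_region_stays_zero(small_grid, periodic_binding):
    kin = KineticParams(D=20.0, b=0.1, c=0.1, g_max=0.2, R=1.0, dt=2e-4)
    model = TwoStateModel(small_grid, kin, periodic_binding)
    empty = LigandState(u=np.zeros(small_grid.n_points),
                        v=np.zeros(small_grid.n_points))
    res = model.simulate_photoconversion(empty, (10.0, 12.0), t_end=0.5)
    assert not res.final.u_lab.any() and not res.final.v_lab.any()


def test_bound_label_frozen_without_exchange(small_grid):
    """With b = c = 0 and no free labelled pool, v_lab cannot change."""
    binding = build_binding_profile(
        small_grid, {"kind": "periodic", "a_max": 10.0, "p1": 2.0, "p2": 0.2})
    kin = KineticParams(D=20.0, b=0.0, c=0.0, g_max=0.0, R=1.0, dt=2e-4)
    model = TwoStateModel(small_grid, kin, binding,
                          SourceProfile(g=np.zeros(small_grid.n_points)))
    v0 = np.where(binding.a > 0, 1.0, 0.0)
    steady = LigandState(u=np.zeros(small_grid.n_points), v=v0)
    res = model.simulate_photoconversion(steady, (0.0, 50.0), t_end=1.0)
    np.testing.assert_allclose(res.final.v_lab, v0, rtol=0, atol=1e-12)


def test_label_region_outside_domain_rejected(small_steady):
    model, result = small_steady
    with pytest.raises(ValueError):
        model.simulate_photoconversion(result.final, (40.0, 60.0), t_end=1.0)


# ---------------------------------------------------------------- refinement

def test_decay_length_insensitive_to_refinement():
    """Halving dt (and separately dx) moves lambda by < 0.5%."""
    from morphodyn.gradient import extract_bound_peaks, fit_decay_length

    def lam(dx, dt, L=300.0):
        grid = SpatialGrid(L=L, dx=dx)
        kin = KineticParams(D=20.0, b=0.1, c=0.1, g_max=0.2, R=1.0, dt=dt)
        binding = build_binding_profile(
            grid, {"kind": "periodic", "a_max": 10.0, "p1": 2.0, "p2": 0.2})
        res = TwoStateModel(grid, kin, binding).simulate(t_end=60.0)
        peaks = extract_bound_peaks(res.final, grid, binding, (1.0, 100.0))
        return fit_decay_length(peaks).lam

    # dt halving at fixed dx, then dx halving at a dt stable for both
    assert abs(lam(0.2, 2e-4) - lam(0.2, 4e-4)) / lam(0.2, 4e-4) < 0.005
    assert abs(lam(0.1, 1e-4) - lam(0.2, 1e-4)) / lam(0.2, 1e-4) < 0.005


def test_monotone_response_to_rates():
    """Faster internalization and no release both steepen the gradient."""
    from morphodyn.gradient import extract_bound_peaks, fit_decay_length

    lams = {}
    for key, b, c in [("base", 0.1, 0.1), ("no_release", 0.0, 0.1),
                      ("fast_internalization", 0.1, 0.3)]:
        grid, kin, binding, result = reduced_reference_run(b, c, L=300.0)
        peaks = extract_bound_peaks(result.final, grid, binding, (1.0, 100.0))
        lams[key] = fit_decay_length(peaks).lam
    assert lams["no_release"] < lams["base"]
    assert lams["fast_internalization"] < lams["base"]
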