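"""Nonstationary integration: closed forms, integrator agreement, oracle checks."""

import numpy as np
import pytest

from conftest import assert_mid_distribution
from isoflux import oracle
from isoflux.observe import group_mid
from isoflux.statespace import build_cumomer_system, build_emu_system
from isoflux.steady import NumericError
from isoflux.transient import (
    PoolSizes,
    inst_sensitivities,
    solve_inst,
    solve_inst_sdirk,
    stationary_limit_check,
)


@pytest.mark.parametrize("integrate", [solve_inst, solve_inst_sdirk])
def test_single_pool_washin_closed_form(fixtures, integrate):
    """x(t) = 1 - exp(-v t / X) for a single washin pool (v=1, X=2)."""
    f = fixtures["washin1"]
    system, _ = build_cumomer_system(f.model)
    t = np.array([0.5, 1.0, 2.0, 4.0])
    traj = integrate(system, f.flux, f.pools, f.model.measurements.experiment("kin").inputs, t)
    for ti in t:
        x = traj.state_at(ti).cumomer("P", 1)
        assert x == pytest.approx(1.0 - np.exp(-ti / 2.0), abs=1e-8)


@pytest.mark.parametrize("integrate", [solve_inst, solve_inst_sdirk])
def test_two_pool_cascade_closed_form(fixtures, integrate):
    """x2(t) = 1 - exp(-t/tau)(1 + t/tau) with tau = X/v = 2."""
    f = fixtures["washin2"]
    system, _ = build_cumomer_system(f.model)
    t = np.array([0.5, 1.0, 2.0, 4.0])
    traj = integrate(system, f.flux, f.pools, f.model.measurements.experiment("kin").inputs, t)
    for ti in t:
        x = traj.state_at(ti).cumomer("P2", 1)
        expected = 1.0 - np.exp(-ti / 2.0) * (1.0 + ti / 2.0)
        assert x == pytest.approx(expected, abs=1e-8)


@pytest.mark.parametrize("build", [build_cumomer_system, build_emu_system])
def test_oracle_equivalence_transient(fixtures, build):
    """Reduced cascades match the full isotopomer ODE on every fixture."""
    for f in fixtures.values():
        if not f.true_pools:
            continue
        system, _ = build(f.model)
        for e in f.model.measurements.experiments:
            groups = [
                f.model.measurements.group(g)
                for g in e.group_ids
                if not f.model.measurements.group(g).stationary
            ]
            if not groups:
                continue
            times = sorted({t for g in groups for t in g.timepoints})
            traj = solve_inst(system, f.flux, f.pools, e.inputs, times)
            otraj = oracle.brute_force_inst(f.model, f.flux, f.pools, e.inputs, times)
            for g in groups:
                n = f.model.pool(g.pool).n_atoms
                for i, t in enumerate(times):
                    mid = group_mid(traj.state_at(t), g)
                    omid = oracle.dist_to_mid(otraj[g.pool][i], n, g.atoms)
                    assert np.max(np.abs(mid - omid)) < 1e-6, (f.name, g.id, t)
                    assert_mid_distribution(mid)


def test_bdf_and_sdirk_agree(fixtures):
    rtol = 1e-8
    for name in ("branch", "cleave_condense", "stiff_pools"):
        f = fixtures[name]
        system, _ = build_cumomer_system(f.model)
        e = next(
            e for e in f.model.measurements.experiments
            if any(not f.model.measurements.group(g).stationary for g in e.group_ids)
        )
        times = sorted({
            t
            for g in e.group_ids
            if not f.model.measurements.group(g).stationary
            for t in f.model.measurements.group(g).timepoints
        })
        t1 = solve_inst(system, f.flux, f.pools, e.inputs, times, rtol=rtol)
        t2 = solve_inst_sdirk(system, f.flux, f.pools, e.inputs, times, rtol=rtol)
        assert np.max(np.abs(t1.ys - t2.ys)) < 10 * rtol * 100  # both error-controlled


def test_stiff_fixture_implicit_beats_explicit(fixtures):
    """On widely spread pool sizes the implicit methods need far fewer steps
    than an explicit Runge-Kutta reference."""
    from scipy.integrate import solve_ivp
    from isoflux.transient import InstProblem

    f = fixtures["stiff_pools"]
    system, _ = build_cumomer_system(f.model)
    e = f.model.measurements.experiment("kin")
    times = [500.0]
    traj = solve_inst_sdirk(system, f.flux, f.pools, e.inputs, times, rtol=1e-6, atol=1e-8)
    prob = InstProblem(system, f.flux, f.pools, e.inputs)
    rk = solve_ivp(
        lambda t, y: prob.f(y), (0, 500.0), prob.unlabeled_y0(), method="RK45",
        rtol=1e-6, atol=1e-8,
    )
    explicit_steps = len(rk.t) - 1
    assert explicit_steps > 100 * (traj.stats["steps"] + traj.stats["rejected"])


def test_sdirk_self_convergence(fixtures):
    """Halving the tolerances changes the output by less than the prior tolerance."""
    f = fixtures["reversible_loop"]
    system, _ = build_cumomer_system(f.model)
    e = f.model.measurements.experiment("kin")
    times = [0.5, 1.5, 3.0]
    prev = None
    for rtol in (1e-6, 5e-7):
        traj = solve_inst_sdirk(system, f.flux, f.pools, e.inputs, times, rtol=rtol,
                                atol=rtol * 1e-2)
        if prev is not None:
            assert np.max(np.abs(traj.ys - prev)) < 1e-6
        prev = traj.ys


def test_washin_sensitivity_closed_forms(fixtures):
    """dx/dX = -(v t/X^2) e^{-vt/X}; dx/dv = (t/X) e^{-vt/X} (balanced direction)."""
    f = fixtures["washin1"]
    system, _ = build_cumomer_system(f.model)
    e = f.model.measurements.experiment("kin")
    traj, sens = inst_sensitivities(
        system, f.flux, f.pools, e.inputs, [2.0],
        [("pool", "P"), ("net", "v1"), ("net", "v2")],
    )
    assert traj.state_at(2.0).cumomer("P", 1) == pytest.approx(1 - np.exp(-1), abs=1e-7)
    dX = sens[0].state_at(2.0).cumomer("P", 1)
    assert dX == pytest.approx(-(2.0 / 4.0) * np.exp(-1), abs=1e-6)
    dv = sens[1].state_at(2.0).cumomer("P", 1) + sens[2].state_at(2.0).cumomer("P", 1)
    assert dv == pytest.approx(np.exp(-1), abs=1e-6)


def test_inst_sensitivities_match_finite_differences(fixtures):
    f = fixtures["reversible_loop"]
    system, _ = build_cumomer_system(f.model)
    e = f.model.measurements.experiment("kin")
    times = [0.6, 2.4]
    params = [("xch", "v2"), ("pool", "B")]
    _, sens = inst_sensitivities(system, f.flux, f.pools, e.inputs, times, params)
    for pi, (kind, pname) in enumerate(params):
        h = 1e-5
        def ys_at(eps):
            xch = dict(f.true_xch)
            pools = dict(f.true_pools)
            if kind == "xch":
                xch[pname] += eps
            else:
                pools[pname] += eps
            fl = f.flux if kind != "xch" else type(f.flux)(
                reactions=f.flux.reactions, net=f.flux.net, xch=np.array(
                    [xch.get(r, 0.0) for r in f.flux.reactions]))
            traj = solve_inst(system, fl, PoolSizes(sizes=pools), e.inputs, times, rtol=1e-10,
                              atol=1e-12)
            return traj.ys
        fd = (ys_at(h) - ys_at(-h)) / (2 * h)
        an = sens[pi].ys
        scale = max(np.max(np.abs(fd)), 1e-9)
        assert np.max(np.abs(fd - an)) / scale < 1e-3


def test_stationary_limit_reached(fixtures):
    for name in ("linchain", "branch", "reversible_loop", "cleave_condense"):
        f = fixtures[name]
        system, _ = build_cumomer_system(f.model)
        e = f.model.measurements.experiments[0]
        report = stationary_limit_check(system, f.flux, f.pools, e.inputs)
        assert report["max_deviation"] < 1e-6, name


def test_stationary_limit_improves_with_horizon(fixtures):
    f = fixtures["reversible_loop"]
    system, _ = build_cumomer_system(f.model)
    e = f.model.measurements.experiment("kin")
    d1 = stationary_limit_check(system, f.flux, f.pools, e.inputs, horizon_factor=5.0)
    d2 = stationary_limit_check(system, f.flux, f.pools, e.inputs, horizon_factor=10.0)
    assert d2["max_deviation"] <= d1["max_deviation"] + 1e-14


def test_tiny_pools_reach_stationarity_quickly(fixtures):
    """In the quasi-steady limit X -> 0 the trajectory hits the stationary values."""
    f = fixtures["linchain"]
    system, _ = build_cumomer_system(f.model)
    e = f.model.measurements.experiment("kin")
    tiny = PoolSizes(sizes={p: 1e-6 for p in f.true_pools})
    report = stationary_limit_check(system, f.flux, tiny, e.inputs)
    assert report["horizon"] < 1e-3
    assert report["max_deviation"] < 1e-6


def test_nonpositive_pool_size_rejected():
    with pytest.raises(ValueError, match="must be > 0"):
        PoolSizes(sizes={"B": 0.0})


def test_integration_failure_is_reported(fixtures):
    f = fixtures["washin1"]
    system, _ = build_cumomer_system(f.model)
    e = f.model.measurements.experiment("kin")
    with pytest.raises(NumericError, match="SDIRK"):
        # absurd max step budget forces a controlled failure
        from isoflux.transient import _sdirk_integrate, InstProblem

        prob = InstProblem(system, f.flux, f.pools, e.inputs)
        _sdirk_integrate(prob.f, prob.jac, prob.unlabeled_y0(), 4.0, np.array([4.0]),
                         1e-12, 1e-14, max_steps=2)
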