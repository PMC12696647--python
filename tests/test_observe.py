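"""Measurement mapping, residuals and the residual Jacobian."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isoflux.model import InputMixture, ModelError
from isoflux.observe import (
    MeasuredData,
    SimulatedData,
    Simulator,
    mid_transform,
    residual_jacobian,
    residuals,
)
from isoflux.statespace import build_cumomer_system
from isoflux.steady import solve_stationary


def test_fully_labeled_input_gives_m2(fixtures):
    f = fixtures["linchain"]
    system, _ = build_cumomer_system(f.model)
    inputs = (InputMixture(pool="A", components=(("11", 1.0),)),)
    state = solve_stationary(system, f.flux, inputs)
    from isoflux.observe import group_mid

    np.testing.assert_allclose(
        group_mid(state, f.model.measurements.group("gC")), [0, 0, 1], atol=1e-12
    )


def test_simulator_batches_experiments(fixtures):
    f = fixtures["mix"]
    sim = Simulator(f.model)
    out = sim.simulate(f.flux, f.pools)
    # both stationary experiments and the transient one are present
    assert set(out.table.experiment) == {"exp1", "exp2", "kin"}
    np.testing.assert_allclose(out.mid("exp1", "gB1", np.inf), [0.25, 0.75], atol=1e-12)
    np.testing.assert_allclose(out.mid("exp2", "gB2", np.inf), [0.75, 0.25], atol=1e-12)


def test_cumomer_and_emu_measurements_identical(fixtures):
    f = fixtures["branch"]
    simc = Simulator(f.model, "cumomer").simulate(f.flux, f.pools)
    sime = Simulator(f.model, "emu").simulate(f.flux, f.pools)
    merged = simc.table.merge(
        sime.table, on=["experiment", "group", "time", "mass_shift"], suffixes=("_c", "_e")
    )
    assert len(merged) == len(simc.table)
    np.testing.assert_allclose(merged.value_c, merged.value_e, atol=1e-8)


def _meas_from(sim: SimulatedData, sd: float = 0.01) -> MeasuredData:
    tab = sim.table.copy()
    tab["sd"] = sd
    return MeasuredData(table=tab)


def test_residuals_zero_for_identical_data(fixtures):
    f = fixtures["linchain"]
    sim = Simulator(f.model).simulate(f.flux, f.pools)
    res = residuals(sim, _meas_from(sim))
    assert res.ssr == 0.0
    assert len(res) == len(sim.table)


def test_residuals_two_sd_off_gives_ssr_four(fixtures):
    f = fixtures["linchain"]
    sim = Simulator(f.model).simulate(f.flux, f.pools)
    meas = _meas_from(sim, sd=0.01)
    meas.table.loc[0, "value"] += 0.02  # 2 sd
    res = residuals(sim, meas)
    assert res.ssr == pytest.approx(4.0, abs=1e-9)


def test_ssr_additive_and_order_invariant(fixtures):
    f = fixtures["mix"]
    sim = Simulator(f.model).simulate(f.flux, f.pools)
    rng = np.random.default_rng(0)
    meas = _meas_from(sim)
    meas.table["value"] += rng.normal(0, 0.01, len(meas.table))
    full = residuals(sim, meas).ssr
    parts = 0.0
    for eid in meas.table.experiment.unique():
        sub = MeasuredData(table=meas.table[meas.table.experiment == eid])
        parts += residuals(sim, sub).ssr
    assert full == pytest.approx(parts, rel=1e-12)
    shuffled = MeasuredData(table=meas.table.sample(frac=1.0, random_state=1))
    assert residuals(sim, shuffled).ssr == pytest.approx(full, rel=1e-12)


def test_missing_mass_shifts_are_dropped(fixtures):
    f = fixtures["linchain"]
    sim = Simulator(f.model).simulate(f.flux, f.pools)
    meas = _meas_from(sim)
    meas = MeasuredData(table=meas.table[meas.table.mass_shift != 1])
    res = residuals(sim, meas)
    assert len(res) == len(sim.table[sim.table.mass_shift != 1])


def test_missing_simulated_value_is_named(fixtures):
    f = fixtures["linchain"]
    sim = Simulator(f.model).simulate(f.flux, f.pools)
    meas = _meas_from(sim)
    extra = meas.table.iloc[[0]].copy()
    extra["time"] = 99.0
    meas = MeasuredData(table=pd.concat([meas.table, extra], ignore_index=True))
    with pytest.raises(ModelError, match="no simulated value.*gC"):
        residuals(sim, meas)


def test_jacobian_scales_inversely_with_sd(fixtures):
    f = fixtures["cleave_condense"]
    sim = Simulator(f.model)
    simdata, dsims = sim.simulate_with_sensitivities(
        f.flux, [("net", "v1"), ("xch", "v2")], f.pools
    )
    m1 = _meas_from(simdata, sd=0.01)
    m2 = _meas_from(simdata, sd=0.02)
    J1 = residual_jacobian(dsims, m1)
    J2 = residual_jacobian(dsims, m2)
    np.testing.assert_allclose(J1, 2.0 * J2, atol=1e-12)


def test_gradient_matches_finite_difference_of_ssr(fixtures):
    """J'r reproduces the finite-difference gradient of SSR/2."""
    f = fixtures["cleave_condense"]
    sim = Simulator(f.model)
    rng = np.random.default_rng(3)
    simdata, dsims = sim.simulate_with_sensitivities(
        f.flux, [("xch", "v2"), ("pool", "D")], f.pools
    )
    meas = _meas_from(simdata)
    meas.table["value"] += rng.normal(0, 0.01, len(meas.table))
    r = residuals(simdata, meas).values
    J = residual_jacobian(dsims, meas)
    grad = J.T @ r
    h = 1e-6
    from isoflux.steady import FluxState
    from isoflux.transient import PoolSizes

    for pi, (kind, pname) in enumerate([("xch", "v2"), ("pool", "D")]):
        def ssr_at(eps):
            xch = dict(f.true_xch)
            pools = dict(f.true_pools)
            if kind == "xch":
                xch[pname] += eps
            else:
                pools[pname] += eps
            fl = FluxState.from_dict(f.model, f.true_net, xch)
            s = sim.simulate(fl, PoolSizes(sizes=pools))
            return 0.5 * residuals(s, meas).ssr
        fd = (ssr_at(h) - ssr_at(-h)) / (2 * h)
        assert grad[pi] == pytest.approx(fd, rel=2e-3, abs=1e-8)


def test_measured_data_csv_roundtrip(fixtures, tmp_path):
    f = fixtures["linchain"]
    sim = Simulator(f.model).simulate(f.flux, f.pools)
    meas = _meas_from(sim)
    path = tmp_path / "data.csv"
    meas.to_csv(path)
    back = MeasuredData.read_csv(path)
    pd.testing.assert_frame_equal(
        back.table.reset_index(drop=True), meas.table.reset_index(drop=True),
        check_dtype=False,
    )
    assert np.isinf(back.table.time).any()  # stationary marker survives


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(1, 3), st.integers(0, 10_000))
def test_mid_transform_inverts_inclusion_exclusion(size, seed):
    """The cumomer->MID transform agrees with direct marginalization of a
    random isotopomer distribution."""
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.ones(2**size))
    # cumomer vector over subset masks: x[m] = sum of p over patterns >= m
    x = np.zeros(2**size)
    for m in range(2**size):
        x[m] = sum(p[i] for i in range(2**size) if i & m == m)
    mid_direct = np.zeros(size + 1)
    for i in range(2**size):
        mid_direct[bin(i).count("1")] += p[i]
    np.testing.assert_allclose(mid_transform(size) @ x, mid_direct, atol=1e-12)
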