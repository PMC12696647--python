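"""Stationary cascade solves, sensitivities and labeling invariants."""

import numpy as np
import pytest

from conftest import assert_mid_distribution
from isoflux import oracle
from isoflux.model import InputMixture, NetworkModel, Pool, Reaction
from isoflux.observe import group_mid
from isoflux.statespace import build_cumomer_system, build_emu_system
from isoflux.steady import (
    FluxState,
    NumericError,
    StationarySolver,
    solve_stationary,
    stationary_sensitivities,
)


def _simple_model(bidirectional=False):
    return NetworkModel(
        name="m",
        pools=(Pool("A", 1, is_substrate=True), Pool("B", 1)),
        reactions=(
            Reaction("v1", educts=(("A", "a"),), products=(("B", "a"),),
                     bidirectional=bidirectional),
            Reaction("v2", educts=(("B", "a"),), products=()),
        ),
    )


MIX_IN = (InputMixture(pool="A", components=(("1", 1.0),)),)


def test_single_pool_fully_labeled():
    model = _simple_model()
    system, _ = build_cumomer_system(model, groups=[_g(model, "B")])
    flux = FluxState.from_dict(model, {"v1": 1.0, "v2": 1.0})
    state = solve_stationary(system, flux, MIX_IN)
    assert state.cumomer("B", 1) == pytest.approx(1.0, abs=1e-12)


def _g(model, pool):
    from isoflux.model import MsGroup

    n = model.pool(pool).n_atoms
    return MsGroup(id=f"g{pool}", pool=pool, atoms=tuple(range(n)),
                   timepoints=None, sd=(0.01,) * (n + 1))


def test_mixing_node_flux_weighted_average(fixtures):
    """B fed by v1=3 labeled and v2=1 unlabeled, consumed by 4: x = 0.75."""
    f = fixtures["mix"]
    system, _ = build_cumomer_system(f.model)
    state = solve_stationary(system, f.flux, f.model.measurements.experiment("exp1").inputs)
    assert state.cumomer("B", 1) == pytest.approx(0.75, abs=1e-12)


def test_linchain_fifty_fifty_mid(fixtures):
    f = fixtures["linchain"]
    system, _ = build_cumomer_system(f.model)
    state = solve_stationary(system, f.flux, f.model.measurements.experiment("stat").inputs)
    mid = group_mid(state, f.model.measurements.group("gC"))
    np.testing.assert_allclose(mid, [0.5, 0.0, 0.5], atol=1e-12)


@pytest.mark.parametrize("build", [build_cumomer_system, build_emu_system])
def test_oracle_equivalence_stationary(fixtures, build):
    """Reduced cascade matches the brute-force isotopomer steady state."""
    for f in fixtures.values():
        system, _ = build(f.model)
        for e in f.model.measurements.experiments:
            groups = [
                f.model.measurements.group(g)
                for g in e.group_ids
                if f.model.measurements.group(g).stationary
            ]
            if not groups:
                continue
            state = solve_stationary(system, f.flux, e.inputs)
            dists = oracle.brute_force_stationary(f.model, f.flux, e.inputs)
            for g in groups:
                n = f.model.pool(g.pool).n_atoms
                omid = oracle.dist_to_mid(dists[g.pool], n, g.atoms)
                np.testing.assert_allclose(group_mid(state, g), omid, atol=1e-9)


def test_reversible_continuity_in_exchange(fixtures):
    """Solutions at xch=0 and xch=1e-12 differ by less than 1e-8."""
    f = fixtures["reversible_loop"]
    system, _ = build_cumomer_system(f.model)
    inputs = f.model.measurements.experiment("stat").inputs
    s0 = solve_stationary(system, FluxState.from_dict(f.model, f.true_net, {"v2": 0.0}), inputs)
    s1 = solve_stationary(system, FluxState.from_dict(f.model, f.true_net, {"v2": 1e-12}), inputs)
    for lev in system.levels:
        np.testing.assert_allclose(
            s0.values[lev.k - 1], s1.values[lev.k - 1], atol=1e-8
        )


def test_mixing_node_sensitivity_closed_form(fixtures):
    """d x_B / d v1 along the balanced direction equals v2/(v1+v2)^2 = 1/16."""
    f = fixtures["mix"]
    system, _ = build_cumomer_system(f.model)
    solver = StationarySolver(system, f.flux)
    state = solver.solve(f.model.measurements.experiment("exp1").inputs)
    # raising v1 with v2 fixed raises the consumption v3 = v1 + v2 as well
    dv1, dv3 = solver.sensitivities(state, [("net", "v1"), ("net", "v3")])
    total = dv1.cumomer("B", 1) + dv3.cumomer("B", 1)
    assert total == pytest.approx(1.0 / 16.0, abs=1e-12)


@pytest.mark.parametrize("build", [build_cumomer_system, build_emu_system])
def test_sensitivities_match_finite_differences(fixtures, build):
    f = fixtures["cleave_condense"]
    system, _ = build(f.model)
    e = f.model.measurements.experiment("stat")
    groups = [f.model.measurements.group(g) for g in e.group_ids]
    solver = StationarySolver(system, f.flux)
    state = solver.solve(e.inputs)
    params = [("net", "v1"), ("xch", "v2")]
    sens = solver.sensitivities(state, params)
    for pi, (kind, rname) in enumerate(params):
        h = 1e-6
        def mid_at(eps):
            net = dict(f.true_net)
            xch = dict(f.true_xch)
            (net if kind == "net" else xch)[rname] += eps
            fl = FluxState.from_dict(f.model, net, xch)
            st = StationarySolver(system, fl).solve(e.inputs)
            return np.concatenate([group_mid(st, g) for g in groups])
        fd = (mid_at(h) - mid_at(-h)) / (2 * h)
        an = np.concatenate([group_mid(sens[pi], g) for g in groups])
        scale = max(np.max(np.abs(fd)), 1e-9)
        assert np.max(np.abs(fd - an)) / scale < 1e-4


def test_pool_size_has_zero_stationary_sensitivity(fixtures):
    """A parameter outside the stationary subsystem has exactly zero sensitivity."""
    f = fixtures["linchain"]
    system, _ = build_cumomer_system(f.model)
    sens = stationary_sensitivities(
        system, f.flux, f.model.measurements.experiment("stat").inputs, [("pool", "B")]
    )
    for lev in system.levels:
        assert np.all(sens[0].values[lev.k - 1] == 0.0)


def test_zero_consumption_raises_structural_singularity():
    model = NetworkModel(
        name="sink",
        pools=(Pool("A", 1, is_substrate=True), Pool("B", 1)),
        reactions=(
            Reaction("v1", educts=(("A", "a"),), products=(("B", "a"),)),
            Reaction("v2", educts=(("B", "a"),), products=()),
        ),
    )
    system, _ = build_cumomer_system(model, groups=[_g(model, "B")])
    flux = FluxState.from_dict(model, {"v1": 1.0, "v2": 0.0})
    with pytest.raises(NumericError, match="zero total consumption"):
        solve_stationary(system, flux, MIX_IN)


def test_labeling_invariants_random_fluxes(fixtures):
    """Cumomers lie in [0,1] and MIDs are distributions for random interior fluxes."""
    from isoflux.infer import parameterize, sample_polytope

    rng = np.random.default_rng(12345)
    for name in ("branch", "cleave_condense", "mix"):
        f = fixtures[name]
        fp = parameterize(f.model)
        if fp.dim:
            thetas, _, _ = sample_polytope(fp.G, fp.h - 1e-3, 10, rng, warmup=200)
        else:
            thetas = np.zeros((1, 0))
        sysc, _ = build_cumomer_system(f.model)
        syse, _ = build_emu_system(f.model)
        for th in thetas:
            flux = fp.flux_state(th)
            for e in f.model.measurements.experiments:
                groups = [
                    f.model.measurements.group(g)
                    for g in e.group_ids
                    if f.model.measurements.group(g).stationary
                ]
                if not groups:
                    continue
                sc = solve_stationary(sysc, flux, e.inputs)
                for lev in sysc.levels:
                    vals = sc.values[lev.k - 1]
                    assert np.all(vals >= -1e-10) and np.all(vals <= 1 + 1e-10)
                se_state = solve_stationary(syse, flux, e.inputs)
                for g in groups:
                    assert_mid_distribution(group_mid(se_state, g))


def test_monotonicity_in_input_labeling(fixtures):
    """More label in the input never lowers a downstream weight-1 cumomer."""
    f = fixtures["linchain"]
    system, _ = build_cumomer_system(f.model)
    prev = None
    for frac in (0.2, 0.4, 0.6, 0.8):
        inputs = (InputMixture(pool="A", components=(("11", frac), ("00", 1 - frac))),)
        state = solve_stationary(system, f.flux, inputs)
        vals = np.array([state.cumomer("B", 1), state.cumomer("C", 1), state.cumomer("C", 3)])
        if prev is not None:
            assert np.all(vals >= prev - 1e-12)
        prev = vals
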