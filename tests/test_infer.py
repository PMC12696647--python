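"""Free-flux parameterization, least-squares fitting, CIs and MCMC sampling."""

from dataclasses import replace

import numpy as np
import pytest

from conftest import stationary_only, zero_noise_data
from isoflux import infer
from isoflux.model import LinearConstraint, stoichiometric_matrix
from isoflux.observe import MeasuredData


def _mix_identifiable(fixtures):
    """Stationary-only mixing fixture with the total uptake pinned."""
    f = fixtures["mix"]
    model = stationary_only(f.model).with_equalities(
        [LinearConstraint(coeffs={"v1": 1.0, "v2": 1.0}, rhs=4.0)]
    )
    return replace(f, model=model)


def test_parameterize_degrees_of_freedom(fixtures):
    assert infer.parameterize(fixtures["linchain"].model).d_net == 1
    assert infer.parameterize(fixtures["mix"].model).d_net == 2
    # an extra fixed-flux equality drops the dimension by one
    pinned = fixtures["mix"].model.with_equalities(
        [LinearConstraint(coeffs={"v1": 1.0}, rhs=3.0)]
    )
    assert infer.parameterize(pinned).d_net == 1


def test_parameterization_satisfies_balances(fixtures):
    """Every theta maps to a net flux vector in the null space of S."""
    for name in ("linchain", "mix", "branch", "cleave_condense"):
        model = fixtures[name].model
        fp = infer.parameterize(model)
        S = stoichiometric_matrix(model).toarray()
        rng = np.random.default_rng(1)
        for _ in range(5):
            th = rng.normal(size=fp.dim)
            nx = len(fp.xch_reactions)
            th[fp.d_net : fp.d_net + nx] = np.abs(th[fp.d_net : fp.d_net + nx])
            flux = fp.flux_state(th)
            assert np.max(np.abs(S @ flux.net)) < 1e-10
            for eq in model.equalities:
                val = sum(c * flux.net[fp.reactions.index(r)] for r, c in eq.coeffs.items())
                assert val == pytest.approx(eq.rhs, abs=1e-10)


def test_infeasible_constraints_reported(fixtures):
    model = fixtures["linchain"].model.with_equalities(
        [
            LinearConstraint(coeffs={"v1": 1.0}, rhs=1.0),
            LinearConstraint(coeffs={"v1": 1.0}, rhs=2.0),
        ]
    )
    with pytest.raises(infer.InfeasibleError):
        infer.parameterize(model)


def test_fit_recovers_mix_and_is_deterministic(fixtures):
    fx = _mix_identifiable(fixtures)
    data = zero_noise_data(fx)
    res1 = infer.fit(fx.model, data, n_starts=3, seed=5)
    res2 = infer.fit(fx.model, data, n_starts=3, seed=5)
    assert res1.ssr < 1e-12
    # v1 = 3, v2 = 1 at the optimum
    net = dict(zip(res1.flux.reactions, res1.flux.net))
    assert net["v1"] == pytest.approx(3.0, abs=1e-5)
    assert net["v2"] == pytest.approx(1.0, abs=1e-5)
    # byte-identical histories for identical seeds
    for e1, e2 in zip(res1.history, res2.history):
        np.testing.assert_array_equal(e1["theta"], e2["theta"])
        assert e1["ssr"] == e2["ssr"] and e1["iterations"] == e2["iterations"]


def test_starts_stay_inside_polytope(fixtures):
    fp = infer.parameterize(fixtures["branch"].model)
    rng = np.random.default_rng(7)
    draws, _, _ = infer.sample_polytope(fp.G, fp.h, 200, rng, warmup=100)
    assert np.all(fp.G @ draws.T <= fp.h[:, None] + 1e-12)


def test_degenerate_routes_reach_equal_ssr_with_different_theta(fixtures):
    """Parallel identical routes: many optima at the same SSR."""
    f = fixtures["degenerate_parallel"]
    data = zero_noise_data(f)
    res = infer.fit(f.model, data, n_starts=4, seed=3)
    ssrs = [e["ssr"] for e in res.history if e.get("converged")]
    thetas = np.array([e["theta"][0] for e in res.history if e.get("converged")])
    assert max(ssrs) < 1e-12
    assert np.ptp(thetas) > 0.05  # distinct split ratios, equally good


def test_linearized_ci_scaling_and_degeneracy(fixtures):
    fx = _mix_identifiable(fixtures)
    data1 = zero_noise_data(fx)
    res1 = infer.fit(fx.model, data1, n_starts=2, seed=1)
    tab2 = data1.table.copy()
    tab2["sd"] = 2 * tab2["sd"]
    res2 = infer.fit(fx.model, MeasuredData(table=tab2), n_starts=2, seed=1)
    lo1, hi1 = infer.linearized_ci(res1, 0)
    lo2, hi2 = infer.linearized_ci(res2, 0)
    assert (hi2 - lo2) == pytest.approx(2 * (hi1 - lo1), rel=1e-3)
    # non-identifiable direction of the parallel-routes fixture is unbounded
    f = fixtures["degenerate_parallel"]
    resd = infer.fit(f.model, zero_noise_data(f), n_starts=2, seed=2)
    assert infer.linearized_ci(resd, "net_dof1") == (-np.inf, np.inf)


def test_uniform_sampler_matches_simplex_centroid():
    """Constant likelihood: coordinate means of the 2-simplex equal 1/3."""
    G = np.array([[-1.0, 0.0], [0.0, -1.0], [1.0, 1.0]])
    h = np.array([0.0, 0.0, 1.0])
    rng = np.random.default_rng(42)
    draws, _, rate = infer.sample_polytope(G, h, 8000, rng, warmup=1000)
    assert np.all(G @ draws.T <= h[:, None] + 1e-12)
    import arviz as az

    for j in range(2):
        ess = float(az.ess(draws[None, :, j]))
        se = draws[:, j].std() / np.sqrt(ess)
        assert abs(draws[:, j].mean() - 1.0 / 3.0) < 3 * se
    assert rate > 0.2


def test_posterior_concentrates_on_least_squares_solution(fixtures):
    """Sharp data: posterior mean approaches the least-squares estimate and
    the posterior spread tracks the measurement noise."""
    fx = _mix_identifiable(fixtures)
    data = zero_noise_data(fx)
    data.table["sd"] = 0.002
    res = infer.fit(fx.model, data, n_starts=2, seed=0)
    ps = infer.sample_posterior(fx.model, data, n_draws=1500, seed=8, warmup=800)
    assert np.all(fx.model is fx.model)
    post_sd = ps.draws[:, 0].std()
    assert abs(ps.mean[0] - res.theta[0]) < 4 * post_sd / np.sqrt(50)
    wide = data.table.copy()
    wide["sd"] = 0.02
    ps_wide = infer.sample_posterior(fx.model, MeasuredData(table=wide), n_draws=1500,
                                     seed=8, warmup=800)
    assert ps_wide.draws[:, 0].std() > 3 * post_sd


def test_multichain_diagnostics(fixtures):
    fx = _mix_identifiable(fixtures)
    data = zero_noise_data(fx)
    ps = infer.sample_posterior(fx.model, data, n_draws=600, seed=21, n_chains=4)
    assert ps.rhat is not None
    assert np.all(np.asarray(ps.rhat) < 1.05)
    assert ps.acceptance_rate > 0.05
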