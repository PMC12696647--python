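"""Flux estimation and Bayesian sampling over the constrained flux space.

The steady-state balance ``S v = 0`` plus user equalities define an affine
set ``net = v0 + N theta_net`` (null-space basis N computed with rational
arithmetic); exchange fluxes and log pool sizes enter as identity blocks.
All bounds map to an inequality system ``G theta <= h`` -- the flux
polytope.  On top of this parameterization the module provides

* multi-start trust-region least squares (starts drawn uniformly from the
  polytope, gradients from the analytic sensitivity systems),
* linearized confidence intervals from the pseudo-inverse of J'J, and
* a hit-and-run Metropolis sampler for the posterior
  ``exp(-SSR/2)`` restricted to the polytope (uniform prior), suitable
  for linearly constrained problems; pool sizes are handled on log scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import sympy
from scipy.optimize import least_squares, linprog
from scipy.stats import norm

from .model import ModelError, NetworkModel, stoichiometric_matrix
from .observe import MeasuredData, ResidualVector, Simulator, residual_jacobian, residuals
from .steady import FluxState
from .transient import PoolSizes

__all__ = [
    "InfeasibleError",
    "FreeParameterization",
    "FitResult",
    "PosteriorSample",
    "parameterize",
    "fit",
    "sample_posterior",
    "sample_polytope",
    "linearized_ci",
]


class InfeasibleError(ModelError):
    """The constraint system admits no (interior) solution."""


@dataclass
class FreeParameterization:
    """Affine map from free parameters theta to fluxes and pool sizes.

    theta is laid out as ``[theta_net (dim d), xch (one per bidirectional
    reaction), log pool sizes]``; ``net = v0 + N @ theta_net`` satisfies
    all equalities for every theta.
    """

    model: NetworkModel
    reactions: tuple[str, ...]
    N: np.ndarray  # (n_reactions, d)
    v0: np.ndarray
    xch_reactions: tuple[str, ...]
    pool_names: tuple[str, ...]
    G: np.ndarray  # (m, dim) inequality system G theta <= h
    h: np.ndarray
    names: tuple[str, ...]

    @property
    def d_net(self) -> int:
        return self.N.shape[1]

    @property
    def dim(self) -> int:
        return self.d_net + len(self.xch_reactions) + len(self.pool_names)

    def split(self, theta: np.ndarray):
        d, nx = self.d_net, len(self.xch_reactions)
        return theta[:d], theta[d : d + nx], theta[d + nx :]

    def flux_state(self, theta: np.ndarray) -> FluxState:
        tn, tx, _ = self.split(np.asarray(theta, dtype=float))
        net = self.v0 + self.N @ tn
        xch = np.zeros(len(self.reactions))
        for i, rname in enumerate(self.xch_reactions):
            xch[self.reactions.index(rname)] = tx[i]
        return FluxState(reactions=self.reactions, net=net, xch=xch)

    def pool_sizes(self, theta: np.ndarray) -> PoolSizes | None:
        _, _, tp = self.split(np.asarray(theta, dtype=float))
        if len(self.pool_names) == 0:
            return None
        return PoolSizes(sizes={p: float(np.exp(v)) for p, v in zip(self.pool_names, tp)})

    def raw_parameters(self) -> list[tuple[str, str]]:
        """Raw parameters whose sensitivities chain into dtheta."""
        return (
            [("net", r) for r in self.reactions]
            + [("xch", r) for r in self.xch_reactions]
            + [("pool", p) for p in self.pool_names]
        )

    def chain_jacobian(self, J_raw: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """Map a Jacobian w.r.t. raw (net, xch, X) parameters onto theta."""
        nr = len(self.reactions)
        nx = len(self.xch_reactions)
        J_net = J_raw[:, :nr] @ self.N
        J_xch = J_raw[:, nr : nr + nx]
        J_pool = J_raw[:, nr + nx :]
        if len(self.pool_names):
            _, _, tp = self.split(theta)
            J_pool = J_pool * np.exp(tp)[None, :]  # d/dlogX = X d/dX
        return np.hstack([J_net, J_xch, J_pool])

    def box_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Tightest axis-aligned bounds implied by the singleton rows of G."""
        lb = np.full(self.dim, -np.inf)
        ub = np.full(self.dim, np.inf)
        for g, hv in zip(self.G, self.h):
            nz = np.nonzero(g)[0]
            if len(nz) != 1:
                continue
            j = nz[0]
            if g[j] > 0:
                ub[j] = min(ub[j], hv / g[j])
            else:
                lb[j] = max(lb[j], hv / g[j])
        return lb, ub

    def general_rows(self) -> tuple[np.ndarray, np.ndarray]:
        keep = [i for i, g in enumerate(self.G) if np.count_nonzero(g) > 1]
        return self.G[keep], self.h[keep]

    def contains(self, theta: np.ndarray, tol: float = 0.0) -> bool:
        return bool(np.all(self.G @ theta <= self.h + tol))


def _rational_nullspace_and_particular(M: sympy.Matrix, rhs: sympy.Matrix):
    try:
        sol, taus = M.gauss_jordan_solve(rhs)
    except ValueError as exc:
        # infeasibility certificate: y with y'M = 0 but y'rhs != 0
        for y in M.T.nullspace():
            if sympy.simplify((y.T * rhs)[0, 0]) != 0:
                raise InfeasibleError(
                    f"inconsistent constraints; certificate row combination {list(y)}"
                ) from exc
        raise InfeasibleError(f"inconsistent constraints: {exc}") from exc
    v0 = sol.subs({t: 0 for t in taus})
    ns = M.nullspace()
    return ns, v0


def parameterize(
    model: NetworkModel,
    pool_names: Sequence[str] = (),
    pool_bounds: tuple[float, float] = (1e-2, 1e2),
) -> FreeParameterization:
    """Construct the free-parameter description of the feasible space.

    ``pool_names`` lists the pools whose (log) sizes are free parameters;
    pass the system pools for nonstationary problems and leave empty for
    purely stationary ones.
    """
    S = stoichiometric_matrix(model).toarray()
    reactions = tuple(r.name for r in model.reactions)
    rows = [[sympy.nsimplify(x, rational=True) for x in row] for row in S]
    rhs = [sympy.Integer(0)] * len(rows)
    for eq in model.equalities:
        row = [sympy.Integer(0)] * len(reactions)
        for rname, c in eq.coeffs.items():
            row[reactions.index(rname)] = sympy.nsimplify(c, rational=True)
        rows.append(row)
        rhs.append(sympy.nsimplify(eq.rhs, rational=True))
    M = sympy.Matrix(rows)
    b = sympy.Matrix(rhs)
    ns, v0s = _rational_nullspace_and_particular(M, b)
    d = len(ns)
    N = np.array([[float(v[i]) for v in ns] for i in range(len(reactions))], dtype=float)
    N = N.reshape(len(reactions), d)
    v0 = np.array([float(v0s[i]) for i in range(len(reactions))], dtype=float)

    xch_reactions = tuple(
        r.name
        for r in model.reactions
        if r.bidirectional and model.xch_bound(r.name) != (0.0, 0.0)
    )
    pool_names = tuple(pool_names)
    dim = d + len(xch_reactions) + len(pool_names)
    names = (
        tuple(f"net_dof{i + 1}" for i in range(d))
        + tuple(f"xch_{r}" for r in xch_reactions)
        + tuple(f"logX_{p}" for p in pool_names)
    )

    G_rows, h_vals = [], []

    def add_row(g: np.ndarray, hv: float) -> None:
        if np.any(g != 0):
            G_rows.append(g)
            h_vals.append(hv)
        elif hv < 0:
            raise InfeasibleError(
                f"constraint 0 <= {hv:.4g} violated by the particular solution "
                "(empty polytope)"
            )

    for j, rname in enumerate(reactions):
        lo, hi = model.net_bound(rname)
        g = np.zeros(dim)
        g[:d] = N[j]
        if np.isfinite(hi):
            add_row(g.copy(), hi - v0[j])
        if np.isfinite(lo):
            add_row(-g.copy(), v0[j] - lo)
    for i, rname in enumerate(xch_reactions):
        lo, hi = model.xch_bound(rname)
        g = np.zeros(dim)
        g[d + i] = 1.0
        add_row(g.copy(), hi if np.isfinite(hi) else np.inf)
        g2 = np.zeros(dim)
        g2[d + i] = -1.0
        add_row(g2, -max(lo, 0.0))
    lo_p, hi_p = np.log(pool_bounds[0]), np.log(pool_bounds[1])
    for i in range(len(pool_names)):
        g = np.zeros(dim)
        g[d + len(xch_reactions) + i] = 1.0
        add_row(g.copy(), hi_p)
        add_row(-g, -lo_p)

    G = np.array(G_rows) if G_rows else np.zeros((0, dim))
    h = np.array(h_vals) if h_vals else np.zeros(0)
    finite = np.isfinite(h)
    return FreeParameterization(
        model=model,
        reactions=reactions,
        N=N,
        v0=v0,
        xch_reactions=xch_reactions,
        pool_names=pool_names,
        G=G[finite],
        h=h[finite],
        names=names,
    )


def chebyshev_center(G: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Center of the largest inscribed ball of ``G x <= h`` (via LP)."""
    m, dim = G.shape
    if dim == 0:
        return np.zeros(0)
    norms = np.linalg.norm(G, axis=1)
    c = np.zeros(dim + 1)
    c[-1] = -1.0
    A = np.hstack([G, norms[:, None]])
    res = linprog(c, A_ub=A, b_ub=h, bounds=[(None, None)] * dim + [(0, None)], method="highs")
    if not res.success or res.x[-1] <= 0:
        raise InfeasibleError("polytope has no interior (Chebyshev radius <= 0)")
    return res.x[:-1]


def _chord(G: np.ndarray, h: np.ndarray, x: np.ndarray, u: np.ndarray) -> tuple[float, float]:
    """Feasible interval [lo, hi] of lambda for x + lambda*u."""
    slack = h - G @ x
    proj = G @ u
    lo, hi = -np.inf, np.inf
    for s, p in zip(slack, proj):
        if p > 1e-14:
            hi = min(hi, s / p)
        elif p < -1e-14:
            lo = max(lo, s / p)
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise InfeasibleError("polytope is unbounded along a sampled direction")
    return lo, hi


def sample_polytope(
    G: np.ndarray,
    h: np.ndarray,
    n_draws: int,
    rng: np.random.Generator,
    log_density: Callable[[np.ndarray], float] | None = None,
    x0: np.ndarray | None = None,
    warmup: int = 1000,
    step_scale: float | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Hit-and-run Metropolis sampling of ``exp(log_density)`` on ``Gx <= h``.

    Proposals move along a uniformly random direction by a normal step
    truncated to the feasible chord (with the exact Hastings correction);
    with ``log_density=None`` the target is the uniform distribution on
    the polytope.  During warmup the step scale adapts toward ~40%
    acceptance and is then frozen.  Returns (draws, log-densities,
    post-warmup acceptance rate); every draw satisfies the constraints.
    """
    dim = G.shape[1]
    if dim == 0:
        return np.zeros((n_draws, 0)), np.zeros(n_draws), 1.0
    x = chebyshev_center(G, h) if x0 is None else np.asarray(x0, dtype=float)
    if np.any(G @ x > h):
        raise InfeasibleError("start point violates the constraints")
    logf = (lambda _:(0.0)) if log_density is None else log_density
    lx = logf(x)
    if step_scale is None:
        # rough polytope diameter from chord lengths at the center
        lens = []
        for _ in range(10):
            u = rng.standard_normal(dim)
            u /= np.linalg.norm(u)
            lo, hi = _chord(G, h, x, u)
            lens.append(hi - lo)
        step_scale = 0.3 * float(np.median(lens))
    draws = np.empty((n_draws, dim))
    logds = np.empty(n_draws)
    accepted = proposed = 0
    s = step_scale
    for it in range(warmup + n_draws):
        u = rng.standard_normal(dim)
        u /= np.linalg.norm(u)
        lo, hi = _chord(G, h, x, u)
        # truncated-normal step along the chord
        a, b = lo / s, hi / s
        lam = min(max(s * _truncnorm_draw(rng, a, b), lo), hi)
        xn = x + lam * u
        ln = logf(xn)
        # Hastings correction: chord seen from xn is shifted by -lam
        z_fwd = norm.cdf(b) - norm.cdf(a)
        z_rev = norm.cdf((hi - lam) / s) - norm.cdf((lo - lam) / s)
        log_alpha = ln - lx + np.log(max(z_fwd, 1e-300)) - np.log(max(z_rev, 1e-300))
        if it >= warmup:
            proposed += 1
        if np.log(rng.uniform()) < log_alpha:
            x, lx = xn, ln
            if it >= warmup:
                accepted += 1
        if it < warmup and (it + 1) % 50 == 0:
            # Robbins-Monro style scale adaptation toward ~0.4 acceptance
            rate_est = min(1.0, np.exp(log_alpha)) if np.isfinite(log_alpha) else 0.0
            s *= np.exp(0.5 * (rate_est - 0.4))
        if it >= warmup:
            draws[it - warmup] = x
            logds[it - warmup] = lx
    rate = accepted / max(proposed, 1)
    if rate == 0.0:
        raise InfeasibleError(
            "sampler accepted no proposal after warmup; review step scale and bounds"
        )
    return draws, logds, rate


def _truncnorm_draw(rng: np.random.Generator, a: float, b: float) -> float:
    # inverse-CDF sampling is adequate at these scales
    Fa, Fb = norm.cdf(a), norm.cdf(b)
    u = rng.uniform(Fa, Fb)
    return float(norm.ppf(min(max(u, 1e-15), 1 - 1e-15)))


@dataclass
class FitResult:
    """Outcome of a multi-start least-squares flux estimation."""

    parameterization: FreeParameterization
    theta: np.ndarray
    ssr: float
    grad_norm: float
    history: list[dict]
    residual: ResidualVector
    jacobian: np.ndarray  # residuals x theta, at the optimum

    @property
    def flux(self) -> FluxState:
        return self.parameterization.flux_state(self.theta)

    @property
    def pools(self) -> PoolSizes | None:
        return self.parameterization.pool_sizes(self.theta)

    @property
    def names(self) -> tuple[str, ...]:
        return self.parameterization.names

    def covariance(self) -> np.ndarray:
        """Linearized parameter covariance: pseudo-inverse of J'J."""
        JTJ = self.jacobian.T @ self.jacobian
        return np.linalg.pinv(JTJ, rcond=1e-12)

    def bse(self) -> np.ndarray:
        JTJ = self.jacobian.T @ self.jacobian
        w, V = np.linalg.eigh(JTJ)
        tol = max(w.max(), 0.0) * 1e-10 + 1e-300
        se = np.empty(len(self.theta))
        for i in range(len(self.theta)):
            null_mass = float(np.sum(V[i, w < tol] ** 2))
            if null_mass > 1e-8:
                se[i] = np.inf
            else:
                se[i] = np.sqrt(np.sum(V[i, w >= tol] ** 2 / w[w >= tol]))
        return se


def _make_objective(
    sim: Simulator, fp: FreeParameterization, data: MeasuredData, penalty_weight: float = 1e4
):
    """Residual+Jacobian evaluator with memoization of the last point."""
    Gg, hg = fp.general_rows()
    raw = fp.raw_parameters()
    cache: dict = {}

    def evaluate(theta: np.ndarray):
        key = np.asarray(theta, dtype=float).tobytes()
        if key in cache:
            return cache[key]
        flux = fp.flux_state(theta)
        pools = fp.pool_sizes(theta)
        simdata, dsims = sim.simulate_with_sensitivities(flux, raw, pools)
        res = residuals(simdata, data)
        J_raw = residual_jacobian(dsims, data)
        J = fp.chain_jacobian(J_raw, theta)
        r = res.values
        if len(Gg):
            viol = penalty_weight * np.maximum(0.0, Gg @ theta - hg)
            r = np.concatenate([r, viol])
            Jg = penalty_weight * Gg * (Gg @ theta - hg > 0)[:, None]
            J = np.vstack([J, Jg])
        cache.clear()
        cache[key] = (r, J, res)
        return cache[key]

    return evaluate


def fit(
    model: NetworkModel,
    data: MeasuredData,
    n_starts: int = 5,
    seed: int = 0,
    representation: str | None = None,
    pool_bounds: tuple[float, float] = (1e-2, 1e2),
    simulator: Simulator | None = None,
    **ls_options,
) -> FitResult:
    """Multi-start bound-constrained least-squares flux (and pool-size) fit.

    Start points are drawn uniformly from the flux polytope (seeded
    hit-and-run); each start is refined with trust-region least squares
    using the analytic residual Jacobian.  Deterministic given
    ``(seed, n_starts, options)``.
    """
    sim = simulator if simulator is not None else Simulator(model, representation)
    pool_names = tuple(sim.system.pools) if sim.needs_pool_sizes() else ()
    fp = parameterize(model, pool_names=pool_names, pool_bounds=pool_bounds)
    rng = np.random.default_rng(seed)
    margin = 1e-6
    # thin the hit-and-run chain so the starts are effectively independent
    # draws from the polytope, not a correlated random walk segment
    thin = 25 * max(fp.dim, 1)
    chain, _, _ = sample_polytope(
        fp.G, fp.h - margin * np.maximum(1.0, np.abs(fp.h)), max(n_starts, 1) * thin, rng,
        warmup=200 + 50 * fp.dim,
    )
    starts = chain[thin - 1 :: thin]
    evaluate = _make_objective(sim, fp, data)
    lb, ub = fp.box_bounds()
    options = dict(xtol=1e-12, ftol=1e-12, gtol=1e-10)
    options.update(ls_options)
    history: list[dict] = []
    best = None
    for i in range(max(n_starts, 1)):
        x0 = np.clip(starts[i], lb + 1e-9, ub - 1e-9)
        try:
            sol = least_squares(
                lambda th: evaluate(th)[0],
                x0,
                jac=lambda th: evaluate(th)[1],
                bounds=(lb, ub),
                method="trf",
                **options,
            )
            entry = {
                "start": x0.copy(),
                "theta": sol.x.copy(),
                "ssr": float(2.0 * sol.cost),
                "converged": bool(sol.success),
                "iterations": int(sol.nfev),
                "message": sol.message,
            }
        except Exception as exc:  # noqa: BLE001 - per-start diagnostics
            entry = {"start": x0.copy(), "converged": False, "error": str(exc)}
        history.append(entry)
        if entry.get("converged") and (best is None or entry["ssr"] < best["ssr"]):
            best = entry
    if best is None:
        raise ModelError(f"all {n_starts} starts failed; history: {history}")
    r, J, res = evaluate(best["theta"])
    n_meas = len(res.values)
    grad = J[:n_meas].T @ r[:n_meas]
    return FitResult(
        parameterization=fp,
        theta=best["theta"],
        ssr=float(res.values @ res.values),
        grad_norm=float(np.linalg.norm(grad)),
        history=history,
        residual=res,
        jacobian=J[:n_meas],
    )


def linearized_ci(fitres: FitResult, parameter: int | str, level: float = 0.95):
    """Approximate confidence interval from the linearized covariance.

    Rank-deficient directions give an unbounded interval rather than an
    exception.  The interval is flagged approximate: it ignores the
    curvature of the residual surface.
    """
    if isinstance(parameter, str):
        parameter = fitres.names.index(parameter)
    se = fitres.bse()[parameter]
    z = norm.ppf(0.5 + level / 2.0)
    c = fitres.theta[parameter]
    if not np.isfinite(se):
        return (-np.inf, np.inf)
    return (c - z * se, c + z * se)


@dataclass
class PosteriorSample:
    """MCMC draws over the free parameters with diagnostics."""

    parameterization: FreeParameterization
    draws: np.ndarray  # (n_chains * n_draws, dim)
    log_density: np.ndarray
    acceptance_rate: float
    seed: int
    n_chains: int
    rhat: np.ndarray | None = None
    ess: np.ndarray | None = None

    @property
    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    def chains(self) -> np.ndarray:
        n = len(self.draws) // self.n_chains
        return self.draws.reshape(self.n_chains, n, -1)


def sample_posterior(
    model: NetworkModel,
    data: MeasuredData | None,
    n_draws: int = 2000,
    seed: int = 0,
    n_chains: int = 1,
    warmup: int | None = None,
    representation: str | None = None,
    pool_bounds: tuple[float, float] = (1e-2, 1e2),
    simulator: Simulator | None = None,
) -> PosteriorSample:
    """Posterior sampling with hit-and-run Metropolis on the flux polytope.

    The log-density is ``-SSR(theta)/2`` (Gaussian measurement likelihood)
    plus a uniform prior over the polytope; with ``data=None`` the target
    is the uniform distribution itself.  Split-Rhat and effective sample
    sizes are computed when more than one chain is run.
    """
    sim = simulator if simulator is not None else Simulator(model, representation)
    pool_names = tuple(sim.system.pools) if sim.needs_pool_sizes() else ()
    fp = parameterize(model, pool_names=pool_names, pool_bounds=pool_bounds)
    if data is None:
        logf = None
    else:
        def logf(theta: np.ndarray) -> float:
            flux = fp.flux_state(theta)
            pools = fp.pool_sizes(theta)
            res = residuals(sim.simulate(flux, pools), data)
            return -0.5 * res.ssr

    if warmup is None:
        warmup = max(500, n_draws // 4)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_chains)
    all_draws, all_logd, rates = [], [], []
    for cs in child_seeds:
        rng = np.random.default_rng(cs)
        d, ld, rate = sample_polytope(fp.G, fp.h, n_draws, rng, log_density=logf, warmup=warmup)
        all_draws.append(d)
        all_logd.append(ld)
        rates.append(rate)
    draws = np.concatenate(all_draws)
    logd = np.concatenate(all_logd)
    rhat = ess = None
    if n_chains >= 2:
        import arviz as az

        chains = np.stack(all_draws)  # (chain, draw, dim)
        idata = az.from_dict(posterior={"theta": chains})
        rhat = az.rhat(idata).theta.values
        ess = az.ess(idata).theta.values
    return PosteriorSample(
        parameterization=fp,
        draws=draws,
        log_density=logd,
        acceptance_rate=float(np.mean(rates)),
        seed=seed,
        n_chains=n_chains,
        rhat=rhat,
        ess=ess,
    )
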