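"""Isotopically nonstationary labeling: stiff ODE integration.

With finite pool sizes the cascade becomes an ODE system

    X_i dx_i/dt = production_i(x, inputs) - consumption_i * x_i,

stacked over all levels into one block-triangular system so that a single
adaptive step controller governs the whole cascade.  Two integrators are
offered: a multistep BDF method (adaptive order and step size) and an
L-stable singly diagonally implicit Runge-Kutta (SDIRK) method of order 3
with an embedded order-2 error estimate.  Both control the local error in
a weighted RMS norm, and both resolve their implicit stage/step equations
with the same sparse LU machinery used for the stationary systems.

Forward sensitivity systems -- linear in the sensitivities and driven by
the state trajectory -- are integrated jointly with the state at the same
tolerances; the per-parameter subsystems are mutually independent given
the state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.integrate import solve_ivp

from .model import InputMixture
from .statespace import CascadeSystem
from .steady import (
    FluxState,
    LabelingState,
    NumericError,
    Parameter,
    StationarySolver,
    _bterm_value,
    _inputs_dict,
)

__all__ = [
    "PoolSizes",
    "Trajectory",
    "InstProblem",
    "solve_inst",
    "solve_inst_sdirk",
    "inst_sensitivities",
    "stationary_limit_check",
]


@dataclass
class PoolSizes:
    """Strictly positive metabolite amounts, in units consistent with flux*time."""

    sizes: dict[str, float]

    def __post_init__(self) -> None:
        for name, x in self.sizes.items():
            if not x > 0:
                raise ValueError(f"pool size for {name!r} must be > 0, got {x}")

    def __getitem__(self, name: str) -> float:
        return self.sizes[name]


@dataclass
class Trajectory:
    """Labeling states on a time grid plus integrator statistics."""

    system: CascadeSystem
    inputs: dict[str, InputMixture]
    t: np.ndarray
    ys: np.ndarray  # (n_times, n_dim) flattened states
    stats: dict = field(default_factory=dict)
    is_derivative: bool = False
    _problem: "InstProblem | None" = None

    def state(self, i: int) -> LabelingState:
        return self._problem.state_from(self.ys[i], is_derivative=self.is_derivative)

    def state_at(self, t: float) -> LabelingState:
        idx = np.nonzero(np.isclose(self.t, t, rtol=1e-12, atol=1e-12))[0]
        if idx.size == 0:
            raise KeyError(f"time {t} not on the trajectory grid")
        return self.state(int(idx[0]))

    def __len__(self) -> int:
        return len(self.t)


class InstProblem:
    """Numeric form of the stacked cascade ODE for one parameter set."""

    def __init__(
        self,
        system: CascadeSystem,
        flux: FluxState,
        pools: PoolSizes,
        inputs: Sequence[InputMixture] | Mapping[str, InputMixture],
    ):
        self.system = system
        self.flux = flux
        self.pools = pools
        self.inputs = _inputs_dict(inputs)
        self.widths = [
            1 if system.representation == "cumomer" else lev.k + 1 for lev in system.levels
        ]
        self.level_start: list[int] = []
        n = 0
        for lev, w in zip(system.levels, self.widths):
            self.level_start.append(n)
            n += lev.n * w
        self.n_dim = n
        self._As = []
        self._Xvecs = []
        self._rates = []
        for lev in system.levels:
            rows, cols, data = [], [], []
            for at in lev.a_terms:
                rows.append(at.row)
                cols.append(at.col)
                data.append(at.coeff * flux.rate(at.rate))
            self._As.append(sp.coo_matrix((data, (rows, cols)), shape=(lev.n, lev.n)).tocsr())
            self._Xvecs.append(np.array([pools[v.pool] for v in lev.variables]))
            self._rates.append([flux.rate(bt.rate) for bt in lev.b_terms])

    # -- state layout ----------------------------------------------------
    def _view(self, y: np.ndarray, k: int) -> np.ndarray:
        lev = self.system.level(k)
        w = self.widths[k - 1]
        start = self.level_start[k - 1]
        block = y[start : start + lev.n * w]
        return block if w == 1 else block.reshape(lev.n, w)

    def offset(self, k: int, i: int) -> int:
        return self.level_start[k - 1] + i * self.widths[k - 1]

    def state_from(self, y: np.ndarray, is_derivative: bool = False) -> LabelingState:
        values = [self._view(y, lev.k) for lev in self.system.levels]
        return LabelingState(self.system, self.inputs, values, is_derivative=is_derivative)

    def unlabeled_y0(self) -> np.ndarray:
        """Tracer-switch initial condition: completely unlabeled network."""
        y0 = np.zeros(self.n_dim)
        if self.system.representation == "emu":
            for lev in self.system.levels:
                for i in range(lev.n):
                    y0[self.offset(lev.k, i)] = 1.0  # all mass at shift 0
        return y0

    # -- right-hand side -------------------------------------------------
    def f(self, y: np.ndarray) -> np.ndarray:
        state = self.state_from(y)
        dy = np.zeros(self.n_dim)
        for lev, A, X, rates in zip(self.system.levels, self._As, self._Xvecs, self._rates):
            if lev.n == 0:
                continue
            x = self._view(y, lev.k)
            if self.system.representation == "cumomer":
                g = -(A @ x)
                for bt, r in zip(lev.b_terms, rates):
                    g[bt.row] += r * _bterm_value(self.system, bt, state)
                self._view(dy, lev.k)[:] = g / X
            else:
                g = -(A @ x)
                for bt, r in zip(lev.b_terms, rates):
                    g[bt.row] += r * _bterm_value(self.system, bt, state)
                self._view(dy, lev.k)[:] = g / X[:, None]
        return dy

    def jac(self, y: np.ndarray) -> sp.csr_matrix:
        """Exact Jacobian df/dy (block lower-triangular)."""
        state = self.state_from(y)
        rows, cols, data = [], [], []
        cum = self.system.representation == "cumomer"
        for lev, A, X, rates in zip(self.system.levels, self._As, self._Xvecs, self._rates):
            if lev.n == 0:
                continue
            k, w = lev.k, self.widths[lev.k - 1]
            Acoo = A.tocoo()
            for r, c, v in zip(Acoo.row, Acoo.col, Acoo.data):
                for q in range(w):
                    rows.append(self.offset(k, r) + q)
                    cols.append(self.offset(k, c) + q)
                    data.append(-v / X[r])
            for bt, rate in zip(lev.b_terms, rates):
                vals = [state.factor_value(ref) for ref in bt.factors]
                for i, ref in enumerate(bt.factors):
                    if ref[0] != "st":
                        continue
                    _, lk, idx = ref
                    if cum:
                        other = rate
                        for j, v in enumerate(vals):
                            if j != i:
                                other *= v
                        rows.append(self.offset(k, bt.row))
                        cols.append(self.offset(lk, idx))
                        data.append(other / X[bt.row])
                    else:
                        conv = np.array([rate])
                        for j, v in enumerate(vals):
                            if j != i:
                                conv = np.convolve(conv, np.atleast_1d(v))
                        s = len(np.atleast_1d(vals[i])) - 1
                        for q in range(k + 1):
                            for lp in range(s + 1):
                                if 0 <= q - lp < len(conv):
                                    rows.append(self.offset(k, bt.row) + q)
                                    cols.append(self.offset(lk, idx) + lp)
                                    data.append(conv[q - lp] / X[bt.row])
        return sp.coo_matrix((data, (rows, cols)), shape=(self.n_dim, self.n_dim)).tocsr()

    def f_param(self, param: Parameter, y: np.ndarray, fy: np.ndarray) -> np.ndarray:
        """Partial derivative of the RHS w.r.t. one raw parameter at fixed state."""
        out = np.zeros(self.n_dim)
        if param[0] == "pool":
            pname = param[1]
            for lev in self.system.levels:
                for i, v in enumerate(lev.variables):
                    if v.pool == pname:
                        o = self.offset(lev.k, i)
                        w = self.widths[lev.k - 1]
                        out[o : o + w] = -fy[o : o + w] / self.pools[pname]
            return out
        state = self.state_from(y)
        for lev, X in zip(self.system.levels, self._Xvecs):
            if lev.n == 0:
                continue
            k, w = lev.k, self.widths[lev.k - 1]
            x = self._view(y, k)
            g = np.zeros(lev.n) if w == 1 else np.zeros((lev.n, w))
            for at in lev.a_terms:
                dr = self.flux.drate(at.rate, param)
                if dr != 0.0:
                    g[at.row] -= at.coeff * dr * x[at.col]
            for bt in lev.b_terms:
                dr = self.flux.drate(bt.rate, param)
                if dr != 0.0:
                    g[bt.row] += dr * _bterm_value(self.system, bt, state)
            view = self._view(out, k)
            view[:] = g / X if w == 1 else g / X[:, None]
        return out


# Local-error control does not bound global error; the BDF wrapper passes a
# tightened tolerance to the stepper so that the delivered accuracy matches
# the requested one on washin-type problems.
_BDF_SAFETY = 0.02


def _prepare_grid(t_eval: Sequence[float]) -> np.ndarray:
    t = np.unique(np.concatenate([[0.0], np.asarray(t_eval, dtype=float)]))
    if np.any(t < 0):
        raise ValueError("timepoints must be non-negative")
    return t


def solve_inst(
    system: CascadeSystem,
    flux: FluxState,
    pools: PoolSizes,
    inputs: Sequence[InputMixture] | Mapping[str, InputMixture],
    t_eval: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
    y0: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the labeling cascade with the adaptive BDF method.

    The initial condition defaults to the unlabeled network (tracer switch
    at t=0).  The returned trajectory is evaluated exactly on
    ``unique([0] + t_eval)``.
    """
    prob = InstProblem(system, flux, pools, inputs)
    t = _prepare_grid(t_eval)
    if y0 is None:
        y0 = prob.unlabeled_y0()
    if t[-1] == 0.0:
        return Trajectory(system, prob.inputs, t, np.array([y0]), {"steps": 0}, _problem=prob)
    sol = solve_ivp(
        lambda _t, y: prob.f(y),
        (0.0, t[-1]),
        y0,
        method="BDF",
        jac=lambda _t, y: prob.jac(y),
        rtol=_BDF_SAFETY * rtol,
        atol=_BDF_SAFETY * atol,
        t_eval=t,
    )
    if not sol.success:
        raise NumericError(
            f"BDF integration failed at t={sol.t[-1] if len(sol.t) else 0:.4g}: "
            f"{sol.message}; consider loosening rtol/atol"
        )
    stats = {"nfev": sol.nfev, "njev": sol.njev, "nlu": sol.nlu, "method": "BDF"}
    return Trajectory(system, prob.inputs, t, sol.y.T.copy(), stats, _problem=prob)


# -- SDIRK ---------------------------------------------------------------
_GAMMA = 0.4358665215084590
_C = np.array([_GAMMA, (1.0 + _GAMMA) / 2.0, 1.0])
_B1 = -1.5 * _GAMMA**2 + 4.0 * _GAMMA - 0.25
_B2 = 1.5 * _GAMMA**2 - 5.0 * _GAMMA + 1.25
_A_TAB = np.array(
    [
        [_GAMMA, 0.0, 0.0],
        [(1.0 - _GAMMA) / 2.0, _GAMMA, 0.0],
        [_B1, _B2, _GAMMA],
    ]
)
_B_TAB = np.array([_B1, _B2, _GAMMA])
_BH2 = (0.5 - _GAMMA) / ((1.0 - _GAMMA) / 2.0)
_BHAT = np.array([1.0 - _BH2, _BH2, 0.0])


def _sdirk_integrate(f, jac, y0, t_end, t_out, rtol, atol, max_steps=100_000):
    """Adaptive 3-stage, order-3, L-stable SDIRK with embedded order-2 estimate.

    Simplified Newton iterations share one sparse LU of ``I - h*gamma*J``
    per step; outputs at ``t_out`` come from cubic Hermite interpolation
    over the accepted steps.
    """
    n = len(y0)
    t, y = 0.0, y0.copy()
    fy = f(y)
    h = min(t_end, 1e-3 * max(t_end, 1.0))
    out = np.empty((len(t_out), n))
    out_i = 0
    while out_i < len(t_out) and t_out[out_i] <= t + 1e-14:
        out[out_i] = y
        out_i += 1
    steps = rejected = nlu = 0
    J = jac(y)
    lu = None
    h_fact = None
    eye = sp.identity(n, format="csc")
    while t < t_end and steps < max_steps:
        h = min(h, t_end - t)
        if lu is None or h_fact != h:
            lu = spla.splu((eye - h * _GAMMA * J).tocsc())
            h_fact = h
            nlu += 1
        K = np.zeros((3, n))
        ok = True
        for i in range(3):
            rhs0 = y + h * sum(_A_TAB[i, j] * K[j] for j in range(i))
            Y = rhs0 + h * _GAMMA * (K[i - 1] if i else fy)
            converged = False
            for _ in range(10):
                G = Y - rhs0 - h * _GAMMA * f(Y)
                dY = lu.solve(-G)
                Y = Y + dY
                sc = atol + rtol * np.abs(Y)
                if np.sqrt(np.mean((dY / sc) ** 2)) < 1e-2:
                    converged = True
                    break
            if not converged:
                ok = False
                break
            K[i] = f(Y)
        if not ok:
            h *= 0.25
            lu = None
            rejected += 1
            continue
        y_new = y + h * (_B_TAB @ K)
        err = h * ((_B_TAB - _BHAT) @ K)
        sc = atol + rtol * np.maximum(np.abs(y), np.abs(y_new))
        err_norm = np.sqrt(np.mean((err / sc) ** 2))
        if err_norm <= 1.0:
            t_new = t + h
            f_new = K[2]  # stiffly accurate: last stage is the step end
            while out_i < len(t_out) and t_out[out_i] <= t_new + 1e-12:
                s = (t_out[out_i] - t) / h
                h00 = (1 + 2 * s) * (1 - s) ** 2
                h10 = s * (1 - s) ** 2
                h01 = s**2 * (3 - 2 * s)
                h11 = s**2 * (s - 1)
                out[out_i] = h00 * y + h10 * h * fy + h01 * y_new + h11 * h * f_new
                out_i += 1
            t, y, fy = t_new, y_new, f_new
            steps += 1
            J = jac(y)
            lu = None
            h = h * min(5.0, max(0.2, 0.9 * err_norm ** (-1.0 / 3.0)))
        else:
            rejected += 1
            h = h * min(1.0, max(0.2, 0.9 * err_norm ** (-1.0 / 3.0)))
            lu = None
    if t < t_end:
        raise NumericError(
            f"SDIRK integration stalled at t={t:.4g}; consider loosening rtol/atol"
        )
    while out_i < len(t_out):
        out[out_i] = y
        out_i += 1
    return out, {"steps": steps, "rejected": rejected, "nlu": nlu, "method": "SDIRK3"}


def solve_inst_sdirk(
    system: CascadeSystem,
    flux: FluxState,
    pools: PoolSizes,
    inputs: Sequence[InputMixture] | Mapping[str, InputMixture],
    t_eval: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
    y0: np.ndarray | None = None,
) -> Trajectory:
    """Same contract as :func:`solve_inst` with the SDIRK integrator."""
    prob = InstProblem(system, flux, pools, inputs)
    t = _prepare_grid(t_eval)
    if y0 is None:
        y0 = prob.unlabeled_y0()
    if t[-1] == 0.0:
        return Trajectory(system, prob.inputs, t, np.array([y0]), {"steps": 0}, _problem=prob)
    ys, stats = _sdirk_integrate(prob.f, prob.jac, y0, t[-1], t, rtol, atol)
    return Trajectory(system, prob.inputs, t, ys, stats, _problem=prob)


def inst_sensitivities(
    system: CascadeSystem,
    flux: FluxState,
    pools: PoolSizes,
    inputs: Sequence[InputMixture] | Mapping[str, InputMixture],
    t_eval: Sequence[float],
    parameters: Sequence[Parameter],
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "BDF",
) -> tuple[Trajectory, list[Trajectory]]:
    """State plus forward-sensitivity trajectories for the given parameters.

    The sensitivity equations are appended to the state system and the
    augmented block system is integrated with the same method and
    tolerances; each parameter's block is independent given the state.
    Returns ``(state_trajectory, [sensitivity_trajectory_per_parameter])``.
    """
    prob = InstProblem(system, flux, pools, inputs)
    t = _prepare_grid(t_eval)
    n, P = prob.n_dim, len(parameters)
    z0 = np.zeros(n * (P + 1))
    z0[:n] = prob.unlabeled_y0()

    def rhs(_t, z):
        y = z[:n]
        fy = prob.f(y)
        J = prob.jac(y)
        out = np.empty_like(z)
        out[:n] = fy
        for p, param in enumerate(parameters):
            s = z[n * (p + 1) : n * (p + 2)]
            out[n * (p + 1) : n * (p + 2)] = J @ s + prob.f_param(param, y, fy)
        return out

    def jac(_t, z):
        J = prob.jac(z[:n])
        return sp.block_diag([J] * (P + 1), format="csc")

    if method == "BDF":
        sol = solve_ivp(
            rhs, (0.0, t[-1]), z0, method="BDF", jac=jac,
            rtol=_BDF_SAFETY * rtol, atol=_BDF_SAFETY * atol, t_eval=t,
        )
        if not sol.success:
            raise NumericError(f"sensitivity integration failed: {sol.message}")
        Z = sol.y.T
        stats = {"nfev": sol.nfev, "nlu": sol.nlu, "method": "BDF"}
    else:
        Z, stats = _sdirk_integrate(
            lambda zz: rhs(0.0, zz), lambda zz: jac(0.0, zz), z0, t[-1], t, rtol, atol
        )
    state_traj = Trajectory(system, prob.inputs, t, Z[:, :n].copy(), stats, _problem=prob)
    sens = [
        Trajectory(
            system,
            prob.inputs,
            t,
            Z[:, n * (p + 1) : n * (p + 2)].copy(),
            stats,
            is_derivative=True,
            _problem=prob,
        )
        for p in range(P)
    ]
    return state_traj, sens


def stationary_limit_check(
    system: CascadeSystem,
    flux: FluxState,
    pools: PoolSizes,
    inputs: Sequence[InputMixture] | Mapping[str, InputMixture],
    horizon_factor: float = 50.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> dict:
    """Integrate to a long horizon and compare against the stationary solve.

    The horizon is ``horizon_factor * max(X) / min(total consumption)``,
    a conservative multiple of the slowest washin time constant.  Returns
    the horizon and the maximum absolute deviation over all state scalars.
    """
    inputs = _inputs_dict(inputs)
    prob = InstProblem(system, flux, pools, inputs)
    consumption = []
    for lev, A in zip(system.levels, prob._As):
        if lev.n:
            consumption.extend(A.diagonal())
    if not consumption:
        return {"horizon": 0.0, "max_deviation": 0.0}
    xmax = max(pools[p] for p in system.pools)
    T = horizon_factor * xmax / min(consumption)
    traj = solve_inst(system, flux, pools, inputs, [T], rtol=rtol, atol=atol)
    y_inf = traj.ys[-1]
    stat = StationarySolver(system, flux).solve(inputs)
    y_stat = np.concatenate(
        [np.asarray(stat.values[lev.k - 1]).ravel() for lev in system.levels]
    ) if system.levels else np.zeros(0)
    dev = float(np.max(np.abs(y_inf - y_stat))) if y_stat.size else 0.0
    return {"horizon": float(T), "max_deviation": dev}
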