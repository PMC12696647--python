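"""Isotopically stationary labeling: cascaded sparse linear solves.

At metabolic and isotopic steady state the cascade reduces to one linear
system per level, ``A_k x_k = b_k``: the diagonal of ``A_k`` carries the
total consumption of each pool, off-diagonal entries carry intra-level
transfer, and ``b_k`` collects input-substrate terms plus bilinear
(cumomer) or convolution (EMU) products of already-solved lower levels.
Levels are solved in ascending order with sparse LU; the factorizations
are cached and reused for all sensitivity right-hand sides and across
experiments sharing the same flux state.

Parameter sensitivities follow by implicit differentiation,

    A_k (dx_k/dp) = db_k/dp - (dA_k/dp) x_k,

solved level by level with the cached LU.  The per-parameter solves are
independent of one another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .model import InputMixture, NetworkModel
from .statespace import BTerm, CascadeSystem, _mask_of

__all__ = [
    "FluxState",
    "LabelingState",
    "NumericError",
    "Parameter",
    "assemble_level",
    "solve_stationary",
    "stationary_sensitivities",
    "StationarySolver",
]

# A differentiable model parameter: ('net', reaction), ('xch', reaction) or
# ('pool', pool).
Parameter = tuple


class NumericError(RuntimeError):
    """Numerical failure in a labeling solve (singular system, solver breakdown)."""


@dataclass
class FluxState:
    """Net/exchange flux coordinates with derived forward/backward rates.

    Coordinates follow the usual net/exchange convention:
    ``fwd = max(net, 0) + xch``,
    ``bwd = max(-net, 0) + xch``, so ``net = fwd - bwd`` and
    ``xch = min(fwd, bwd) >= 0``.  Irreversible reactions must have
    ``xch = 0`` and ``net >= 0``.
    """

    reactions: tuple[str, ...]
    net: np.ndarray
    xch: np.ndarray
    _idx: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.net = np.asarray(self.net, dtype=float)
        self.xch = np.asarray(self.xch, dtype=float)
        if self.net.shape != (len(self.reactions),) or self.xch.shape != self.net.shape:
            raise ValueError("net/xch must have one entry per reaction")
        if np.any(self.xch < 0):
            raise ValueError("exchange fluxes must be non-negative")
        self._idx = {n: i for i, n in enumerate(self.reactions)}

    @classmethod
    def from_dict(
        cls,
        model: NetworkModel,
        net: Mapping[str, float],
        xch: Mapping[str, float] | None = None,
    ) -> "FluxState":
        names = tuple(r.name for r in model.reactions)
        nv = np.array([net[n] for n in names], dtype=float)
        xv = np.array([(xch or {}).get(n, 0.0) for n in names], dtype=float)
        for r in model.reactions:
            if not r.bidirectional:
                if xv[names.index(r.name)] != 0.0:
                    raise ValueError(f"irreversible reaction {r.name!r} with nonzero exchange")
                if nv[names.index(r.name)] < 0:
                    raise ValueError(f"irreversible reaction {r.name!r} with negative net flux")
        return cls(reactions=names, net=nv, xch=xv)

    @property
    def fwd(self) -> np.ndarray:
        return np.maximum(self.net, 0.0) + self.xch

    @property
    def bwd(self) -> np.ndarray:
        return np.maximum(-self.net, 0.0) + self.xch

    def rate(self, ref: tuple[str, str]) -> float:
        kind, name = ref
        i = self._idx[name]
        return float(self.fwd[i] if kind == "fwd" else self.bwd[i])

    def drate(self, ref: tuple[str, str], param: Parameter) -> float:
        """Derivative of a forward/backward rate w.r.t. a net or xch coordinate."""
        kind, name = ref
        pk, pname = param
        if pk == "pool" or pname != name:
            return 0.0
        i = self._idx[name]
        if pk == "xch":
            return 1.0
        s = self.net[i]
        dfwd = 1.0 if s > 0 else (0.5 if s == 0 else 0.0)
        return dfwd if kind == "fwd" else dfwd - 1.0


@dataclass
class LabelingState:
    """Per-level solution vectors with accessors by cumomer mask or EMU fragment.

    For derivative states (sensitivities) the constant and input entries
    are identically zero.
    """

    system: CascadeSystem
    inputs: dict[str, InputMixture]
    values: list[np.ndarray]
    is_derivative: bool = False

    @property
    def representation(self) -> str:
        return self.system.representation

    def factor_value(self, ref):
        """Value of a source-term factor: input fragment or state variable."""
        kind = ref[0]
        if kind == "in":
            _, pool, atoms = ref
            if self.is_derivative:
                if self.representation == "cumomer":
                    return 0.0
                return np.zeros(len(atoms) + 1)
            mix = self.inputs[pool]
            if self.representation == "cumomer":
                return mix.cumomer_value(_mask_of(atoms))
            return mix.mid(atoms)
        _, k, i = ref
        return self.values[k - 1][i]

    def cumomer(self, pool: str, mask: int) -> float:
        if mask == 0:
            return 0.0 if self.is_derivative else 1.0
        p = self.system.model.pool(pool)
        if p.is_substrate:
            return 0.0 if self.is_derivative else self.inputs[pool].cumomer_value(mask)
        k, i = self.system.var_index[(pool, mask)]
        return float(self.values[k - 1][i])

    def emu_mid(self, pool: str, atoms: Sequence[int]) -> np.ndarray:
        atoms = tuple(atoms)
        p = self.system.model.pool(pool)
        if p.is_substrate:
            if self.is_derivative:
                return np.zeros(len(atoms) + 1)
            return self.inputs[pool].mid(atoms)
        k, i = self.system.var_index[(pool, atoms)]
        return np.asarray(self.values[k - 1][i])


def _inputs_dict(inputs: Sequence[InputMixture] | Mapping[str, InputMixture]) -> dict:
    if isinstance(inputs, Mapping):
        return dict(inputs)
    return {m.pool: m for m in inputs}


def _bterm_value(system: CascadeSystem, bt: BTerm, state: LabelingState):
    """Product (cumomer) or convolution (EMU) of the source-term factors."""
    if system.representation == "cumomer":
        val = 1.0
        for ref in bt.factors:
            val *= state.factor_value(ref)
        return val
    vec = np.array([1.0])
    for ref in bt.factors:
        vec = np.convolve(vec, state.factor_value(ref))
    return vec


def _bterm_derivative(system: CascadeSystem, bt: BTerm, state: LabelingState, dstate: LabelingState):
    """Derivative of the factor product by the product rule (rate held fixed)."""
    vals = [state.factor_value(ref) for ref in bt.factors]
    dvals = [dstate.factor_value(ref) for ref in bt.factors]
    if system.representation == "cumomer":
        out = 0.0
        for i in range(len(vals)):
            term = dvals[i]
            for j, v in enumerate(vals):
                if j != i:
                    term *= v
            out += term
        return out
    k = sum(len(np.atleast_1d(v)) - 1 for v in vals)
    out = np.zeros(k + 1)
    for i in range(len(vals)):
        vec = np.atleast_1d(dvals[i])
        for j, v in enumerate(vals):
            if j != i:
                vec = np.convolve(vec, np.atleast_1d(v))
        out += vec
    return out


def assemble_level(
    system: CascadeSystem,
    k: int,
    flux: FluxState,
    lower: LabelingState,
    inputs: Sequence[InputMixture] | Mapping[str, InputMixture] | None = None,
):
    """Assemble the level-k balance system ``A_k x_k = b_k``.

    ``lower`` must hold the solutions of levels < k (its ``values`` beyond
    level k-1 are ignored).  Returns ``(A, b)`` with ``A`` sparse CSC and
    ``b`` a vector (cumomer) or an ``n x (k+1)`` MID block (EMU).
    """
    if inputs is not None:
        lower = LabelingState(system, _inputs_dict(inputs), lower.values)
    lev = system.level(k)
    n = lev.n
    rows, cols, data = [], [], []
    diag = np.zeros(n)
    for at in lev.a_terms:
        v = at.coeff * flux.rate(at.rate)
        rows.append(at.row)
        cols.append(at.col)
        data.append(v)
        if at.row == at.col and at.coeff > 0:
            diag[at.row] += v
    maxflux = max(np.max(np.abs(flux.fwd)), np.max(np.abs(flux.bwd)), 1.0)
    bad = np.nonzero(diag < 1e-12 * maxflux)[0]
    if bad.size:
        pool = lev.variables[bad[0]].pool
        raise NumericError(
            f"level {k}: pool {pool!r} has (near-)zero total consumption; "
            "the labeling system is structurally singular"
        )
    A = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsc()
    if system.representation == "cumomer":
        b = np.zeros(n)
    else:
        b = np.zeros((n, k + 1))
    for bt in lev.b_terms:
        b[bt.row] += flux.rate(bt.rate) * _bterm_value(system, bt, lower)
    return A, b


class StationarySolver:
    """Solves the stationary cascade for one flux state, caching the LU.

    The level matrices depend only on fluxes, so one factorization serves
    every input mixture (multi-experiment batching) and every sensitivity
    right-hand side.
    """

    def __init__(self, system: CascadeSystem, flux: FluxState):
        self.system = system
        self.flux = flux
        self._lus: list = [None] * len(system.levels)
        self._As: list = [None] * len(system.levels)

    def _factorize(self, k: int, lower: LabelingState):
        if self._lus[k - 1] is None:
            A, _ = assemble_level(self.system, k, self.flux, lower)
            self._As[k - 1] = A
            try:
                self._lus[k - 1] = spla.splu(A)
            except RuntimeError as exc:  # pragma: no cover - defensive
                pool = self.system.level(k).variables[0].pool
                raise NumericError(f"level {k} (pool {pool!r}): singular matrix: {exc}") from exc
        return self._As[k - 1], self._lus[k - 1]

    def solve(self, inputs: Sequence[InputMixture] | Mapping[str, InputMixture]) -> LabelingState:
        sysd = self.system
        state = LabelingState(sysd, _inputs_dict(inputs), [None] * len(sysd.levels))
        for lev in sysd.levels:
            k = lev.k
            if lev.n == 0:
                state.values[k - 1] = (
                    np.zeros(0) if sysd.representation == "cumomer" else np.zeros((0, k + 1))
                )
                continue
            A, lu = self._factorize(k, state)
            b = np.zeros(lev.n) if sysd.representation == "cumomer" else np.zeros((lev.n, k + 1))
            for bt in lev.b_terms:
                b[bt.row] += self.flux.rate(bt.rate) * _bterm_value(sysd, bt, state)
            x = lu.solve(b)
            resid = np.max(np.abs(A @ x - b)) if b.size else 0.0
            scale = max(np.max(np.abs(b)), 1e-300) if b.size else 1.0
            if b.size and resid > 1e-10 * max(scale, 1.0):
                pool = lev.variables[0].pool
                raise NumericError(
                    f"level {k} (pool {pool!r}): residual {resid:.2e} exceeds tolerance"
                )
            state.values[k - 1] = x
        return state

    def sensitivities(
        self, state: LabelingState, parameters: Sequence[Parameter]
    ) -> list[LabelingState]:
        """One derivative state per parameter, reusing the cached LU."""
        sysd = self.system
        out = []
        for param in parameters:
            dstate = LabelingState(
                sysd, state.inputs, [None] * len(sysd.levels), is_derivative=True
            )
            for lev in sysd.levels:
                k = lev.k
                if lev.n == 0:
                    dstate.values[k - 1] = (
                        np.zeros(0) if sysd.representation == "cumomer" else np.zeros((0, k + 1))
                    )
                    continue
                _, lu = self._factorize(k, state)
                rhs = (
                    np.zeros(lev.n)
                    if sysd.representation == "cumomer"
                    else np.zeros((lev.n, k + 1))
                )
                # db/dp
                for bt in lev.b_terms:
                    rate = self.flux.rate(bt.rate)
                    dr = self.flux.drate(bt.rate, param)
                    if dr != 0.0:
                        rhs[bt.row] += dr * _bterm_value(sysd, bt, state)
                    rhs[bt.row] += rate * _bterm_derivative(sysd, bt, state, dstate)
                # -(dA/dp) x
                xk = state.values[k - 1]
                for at in lev.a_terms:
                    dr = self.flux.drate(at.rate, param)
                    if dr != 0.0:
                        rhs[at.row] -= at.coeff * dr * xk[at.col]
                dstate.values[k - 1] = lu.solve(rhs)
            out.append(dstate)
        return out


def solve_stationary(
    system: CascadeSystem,
    flux: FluxState,
    inputs: Sequence[InputMixture] | Mapping[str, InputMixture],
) -> LabelingState:
    """Solve the stationary cascade level by level with sparse LU."""
    return StationarySolver(system, flux).solve(inputs)


def stationary_sensitivities(
    system: CascadeSystem,
    flux: FluxState,
    inputs: Sequence[InputMixture] | Mapping[str, InputMixture],
    parameters: Sequence[Parameter],
) -> list[LabelingState]:
    """Stationary labeling derivatives w.r.t. the given parameters.

    Pool-size parameters have identically zero stationary sensitivity.
    """
    solver = StationarySolver(system, flux)
    state = solver.solve(inputs)
    return solver.sensitivities(state, parameters)
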