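"""Ground truth: the full, unreduced isotopomer-level simulator.

Every pool with n traced atoms carries all 2**n isotopomer fractions; no
cumomer/EMU compression, no essential-variable reduction.  The stationary
balance is solved by plain fixed-point iteration and the transient system
by a generic stiff integrator at tight tolerance, deliberately sharing no
machinery with the cascade solvers so it can serve as an independent
oracle for them.  A guard keeps the total variable count small.

Conventions: isotopomer patterns are binary strings in canonical order
(``"10"`` = first atom 13C); pattern index i has atom j labeled iff bit
``n-1-j`` of i is set, matching :func:`isoflux.statespace.enumerate_isotopomers`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .model import InputMixture, NetworkModel
from .steady import FluxState, _inputs_dict
from .transient import PoolSizes

__all__ = [
    "IsotopomerSystem",
    "brute_force_stationary",
    "brute_force_inst",
    "dist_to_cumomer",
    "dist_to_mid",
]

GUARD = 4096


def dist_to_cumomer(dist: np.ndarray, n_atoms: int, mask: int) -> float:
    """Cumomer value (all atoms of ``mask`` labeled) from an isotopomer distribution."""
    total = 0.0
    for i, frac in enumerate(dist):
        imask = _index_to_mask(i, n_atoms)
        if imask & mask == mask:
            total += frac
    return total


def dist_to_mid(dist: np.ndarray, n_atoms: int, atoms: Sequence[int]) -> np.ndarray:
    """Fragment MID over ``atoms`` (0-based) from an isotopomer distribution."""
    out = np.zeros(len(atoms) + 1)
    for i, frac in enumerate(dist):
        imask = _index_to_mask(i, n_atoms)
        shift = sum(1 for a in atoms if imask >> a & 1)
        out[shift] += frac
    return out


def _index_to_mask(i: int, n_atoms: int) -> int:
    """Pattern index -> atom bitset (bit j = atom j)."""
    mask = 0
    for j in range(n_atoms):
        if i >> (n_atoms - 1 - j) & 1:
            mask |= 1 << j
    return mask


def _mixture_dist(mix: InputMixture, n_atoms: int) -> np.ndarray:
    dist = np.zeros(2**n_atoms)
    for pattern, frac in mix.components:
        idx = int(pattern, 2) if pattern else 0
        dist[idx] += frac
    return dist


class IsotopomerSystem:
    """Full isotopomer balance equations of a (small) network."""

    def __init__(self, model: NetworkModel, guard: int = GUARD):
        total = sum(2**p.n_atoms for p in model.pools if not p.is_substrate and p.n_atoms > 0)
        if total > guard:
            raise ValueError(f"{total} isotopomer variables exceed the guard of {guard}")
        self.model = model
        self.state_pools = [
            p.name for p in model.pools if not p.is_substrate and p.n_atoms > 0
        ]
        self.n_atoms = {p.name: p.n_atoms for p in model.pools}
        self._compile()

    def _compile(self) -> None:
        """Precompute, per transition, the educt-combination index tables."""
        self._trans = []
        for t in self.model.transitions():
            sizes = [2 ** self.n_atoms[p] for p, _ in t.educts]
            combos = int(np.prod(sizes)) if sizes else 1
            grid = np.indices(sizes).reshape(len(sizes), -1) if sizes else np.zeros((0, 1), int)
            # product pattern index per combo, per product occurrence
            prod_idx = []
            for pname, cfg in t.products:
                n_p = self.n_atoms[pname]
                idx = np.zeros(combos, dtype=int)
                for pos, letter in enumerate(cfg):
                    # locate the educt occurrence and position carrying this letter
                    for e, (ep, ecfg) in enumerate(t.educts):
                        j = ecfg.find(letter)
                        if j >= 0:
                            bit = grid[e] >> (self.n_atoms[ep] - 1 - j) & 1
                            idx |= bit << (n_p - 1 - pos)
                            break
                prod_idx.append((pname, idx))
            self._trans.append(
                {
                    "rate_ref": (t.rate, t.reaction),
                    "educts": [(p, grid[e]) for e, (p, _) in enumerate(t.educts)],
                    "products": prod_idx,
                }
            )

    def _distributions(
        self, y: np.ndarray, inputs: Mapping[str, InputMixture]
    ) -> dict[str, np.ndarray]:
        dists: dict[str, np.ndarray] = {}
        off = 0
        for pname in self.state_pools:
            n = 2 ** self.n_atoms[pname]
            dists[pname] = y[off : off + n]
            off += n
        for p in self.model.pools:
            if p.is_substrate:
                dists[p.name] = _mixture_dist(inputs[p.name], p.n_atoms)
            elif p.n_atoms == 0:
                dists[p.name] = np.array([1.0])
        return dists

    def _production_consumption(
        self, dists: Mapping[str, np.ndarray], flux: FluxState
    ) -> tuple[dict[str, np.ndarray], dict[str, float]]:
        prod = {p: np.zeros(2 ** self.n_atoms[p]) for p in self.state_pools}
        cons = {p: 0.0 for p in self.state_pools}
        for tr in self._trans:
            rate = flux.rate(tr["rate_ref"])
            if rate == 0.0:
                continue
            fracs = np.ones(len(tr["educts"][0][1]) if tr["educts"] else 1)
            for pname, idx in tr["educts"]:
                fracs = fracs * dists[pname][idx]
                if pname in cons:
                    cons[pname] += rate
            for pname, idx in tr["products"]:
                if pname in prod:
                    np.add.at(prod[pname], idx, rate * fracs)
        return prod, cons

    def n_vars(self) -> int:
        return sum(2 ** self.n_atoms[p] for p in self.state_pools)

    def unlabeled_y0(self) -> np.ndarray:
        y0 = np.zeros(self.n_vars())
        off = 0
        for pname in self.state_pools:
            y0[off] = 1.0  # pattern 00..0
            off += 2 ** self.n_atoms[pname]
        return y0


def brute_force_stationary(
    model: NetworkModel,
    flux: FluxState,
    inputs: Sequence[InputMixture] | Mapping[str, InputMixture],
    tol: float = 1e-12,
    max_iter: int = 200_000,
) -> dict[str, np.ndarray]:
    """Stationary isotopomer distributions by fixed-point iteration.

    Iterates ``p_P <- production_P / consumption_P`` pool-wise until the
    update falls below ``tol``; converges geometrically for any strictly
    positive consumption.
    """
    inputs = _inputs_dict(inputs)
    sysd = IsotopomerSystem(model)
    y = sysd.unlabeled_y0()
    for _ in range(max_iter):
        dists = sysd._distributions(y, inputs)
        prod, cons = sysd._production_consumption(dists, flux)
        y_new = np.concatenate(
            [prod[p] / cons[p] if cons[p] > 0 else prod[p] * np.nan for p in sysd.state_pools]
        )
        if np.any(~np.isfinite(y_new)):
            raise RuntimeError("a pool has zero consumption; stationary state undefined")
        delta = np.max(np.abs(y_new - y))
        y = y_new
        if delta < tol:
            dists = sysd._distributions(y, inputs)
            return {p: dists[p].copy() for p in sysd.state_pools}
    raise RuntimeError(f"fixed-point iteration did not converge below {tol}")


def brute_force_inst(
    model: NetworkModel,
    flux: FluxState,
    pools: PoolSizes,
    inputs: Sequence[InputMixture] | Mapping[str, InputMixture],
    t_eval: Sequence[float],
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> dict[str, np.ndarray]:
    """Transient isotopomer distributions on a time grid (stiff integration).

    Returns per pool an array of shape ``(len(t_eval), 2**n_atoms)``.
    """
    inputs = _inputs_dict(inputs)
    sysd = IsotopomerSystem(model)
    t_eval = np.asarray(t_eval, dtype=float)

    def rhs(_t, y):
        dists = sysd._distributions(y, inputs)
        prod, cons = sysd._production_consumption(dists, flux)
        dy = np.empty_like(y)
        off = 0
        for pname in sysd.state_pools:
            n = 2 ** sysd.n_atoms[pname]
            dy[off : off + n] = (prod[pname] - cons[pname] * y[off : off + n]) / pools[pname]
            off += n
        return dy

    sol = solve_ivp(
        rhs, (0.0, float(t_eval[-1])), sysd.unlabeled_y0(), method="BDF",
        rtol=rtol, atol=atol, t_eval=t_eval,
    )
    if not sol.success:
        raise RuntimeError(f"oracle integration failed: {sol.message}")
    out: dict[str, np.ndarray] = {}
    off = 0
    for pname in sysd.state_pools:
        n = 2 ** sysd.n_atoms[pname]
        out[pname] = sol.y[off : off + n].T.copy()
        off += n
    return out
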