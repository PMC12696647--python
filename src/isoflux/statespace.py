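"""Dimension-reduced labeling state spaces: cumomer cascades and EMU graphs.

Starting from the atom-mapped network and the measurement configuration,
this module derives the two classical compressed descriptions of the
isotopomer balance equations:

* **Cumomers** — for each pool, the probability that a given atom subset is
  fully 13C-labeled.  Balances decouple by subset weight into a cascade:
  the weight-k system is linear given all weights < k, with bilinear
  products of lower-weight cumomers as sources wherever a reaction joins
  atoms from several educts.

* **EMUs** (elementary metabolite units) — atom subsets whose state is a
  mass-isotopomer distribution (MID).  The EMU graph is built backward
  from the measured fragments; condensation reactions contribute
  convolutions of smaller EMU MIDs and the cascade is ordered by EMU size.

Only *essential* variables are kept: those backward-reachable from the
measured fragments through the atom transitions.  Both representations
yield a :class:`CascadeSystem` with identical term structure, so the
solvers downstream are representation-agnostic; a scalar-count heuristic
picks between them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Sequence

from .model import MsGroup, NetworkModel, SemanticError, Transition

__all__ = [
    "Cumomer",
    "Emu",
    "ATerm",
    "BTerm",
    "Level",
    "CascadeSystem",
    "ReductionReport",
    "enumerate_isotopomers",
    "build_cumomer_system",
    "build_emu_system",
    "choose_representation",
]

# A factor in a bilinear/convolution source term: either an input-substrate
# fragment ('in', pool, atoms) whose value follows from the input mixture, or
# a state variable ('st', level, index) solved at a lower (or equal) level.
Factor = tuple


@dataclass(frozen=True)
class Cumomer:
    pool: str
    mask: int  # bitset over the pool's atoms, bit i = atom i (0-based)

    @property
    def weight(self) -> int:
        return self.mask.bit_count()

    @property
    def atoms(self) -> tuple[int, ...]:
        return tuple(i for i in range(self.mask.bit_length()) if self.mask >> i & 1)


@dataclass(frozen=True)
class Emu:
    pool: str
    atoms: tuple[int, ...]  # sorted, 0-based

    @property
    def size(self) -> int:
        return len(self.atoms)


@dataclass(frozen=True)
class ATerm:
    """Intra-level matrix entry: A[row, col] += coeff * rate."""

    row: int
    col: int
    rate: tuple[str, str]  # ('fwd'|'bwd', reaction name)
    coeff: float


@dataclass(frozen=True)
class BTerm:
    """Source term: b[row] += rate * product/convolution of factor values."""

    row: int
    rate: tuple[str, str]
    factors: tuple[Factor, ...]


@dataclass
class Level:
    k: int
    variables: list  # Cumomer or Emu instances
    a_terms: list[ATerm] = field(default_factory=list)
    b_terms: list[BTerm] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.variables)


@dataclass
class CascadeSystem:
    """A leveled, sparse, symbolic description of the labeling balances.

    ``levels[k-1]`` holds the weight-/size-k subsystem; intra-level
    coupling is linear (``a_terms``) while ``b_terms`` reference only
    inputs and strictly lower levels, so the cascade is solvable level by
    level (stationary case) or integrable as one block-triangular ODE
    (nonstationary case).
    """

    representation: str  # 'cumomer' | 'emu'
    model: NetworkModel
    levels: list[Level]
    var_index: dict  # (pool, key) -> (k, idx); key: mask int or atoms tuple

    @property
    def n_state_vars(self) -> int:
        return sum(lev.n for lev in self.levels)

    @property
    def n_state_scalars(self) -> int:
        if self.representation == "cumomer":
            return self.n_state_vars
        return sum(len(v.atoms) + 1 for lev in self.levels for v in lev.variables)

    def level(self, k: int) -> Level:
        return self.levels[k - 1]

    def var_pools(self, k: int) -> list[str]:
        return [v.pool for v in self.level(k).variables]

    def per_level_sizes(self) -> list[int]:
        return [lev.n for lev in self.levels]

    @property
    def pools(self) -> list[str]:
        """Names of pools carrying at least one state variable."""
        seen: list[str] = []
        for lev in self.levels:
            for v in lev.variables:
                if v.pool not in seen:
                    seen.append(v.pool)
        return seen


@dataclass
class ReductionReport:
    representation: str
    full_variables: int
    essential_variables: int
    per_level_sizes: list[int]
    scalar_unknowns: int
    reason: str = ""

    def to_dict(self) -> dict:
        return {
            "representation": self.representation,
            "full_variables": self.full_variables,
            "essential_variables": self.essential_variables,
            "per_level_sizes": self.per_level_sizes,
            "scalar_unknowns": self.scalar_unknowns,
            "reason": self.reason,
        }


def enumerate_isotopomers(model: NetworkModel, guard: int = 4096) -> dict[str, list[str]]:
    """All 2**n isotopomer patterns per pool, in canonical binary order.

    Supports the brute-force oracle; guarded so it is only used on small
    networks.
    """
    total = sum(2 ** p.n_atoms for p in model.pools)
    if total > guard:
        raise ValueError(f"isotopomer enumeration of {total} variables exceeds guard {guard}")
    out = {}
    for p in model.pools:
        if p.n_atoms == 0:
            out[p.name] = [""]
        else:
            out[p.name] = [format(i, f"0{p.n_atoms}b") for i in range(2 ** p.n_atoms)]
    return out


def _state_pools(model: NetworkModel) -> set[str]:
    """Pools that carry labeling state (not substrates, traced atoms > 0)."""
    return {p.name for p in model.pools if p.n_atoms > 0 and not p.is_substrate}


def _trace_sources(
    t: Transition, prod_idx: int, atoms: Sequence[int]
) -> list[tuple[str, tuple[int, ...]]]:
    """Trace product atoms back to educt occurrences.

    Returns one ``(educt_pool, educt_atom_subset)`` entry per educt
    occurrence that contributes at least one of the requested product
    atoms.  The subsets partition ``atoms`` by atom conservation.
    """
    _, cfg = t.products[prod_idx]
    letters = {cfg[i] for i in atoms}
    out = []
    for ep, ecfg in t.educts:
        sub = tuple(j for j, c in enumerate(ecfg) if c in letters)
        if sub:
            out.append((ep, sub))
    return out


def _mask_of(atoms: Sequence[int]) -> int:
    m = 0
    for a in atoms:
        m |= 1 << a
    return m


def _atoms_of(mask: int) -> tuple[int, ...]:
    return tuple(i for i in range(mask.bit_length()) if mask >> i & 1)


def _seed_keys(model: NetworkModel, groups: Sequence[MsGroup], representation: str):
    """State variables directly required to evaluate the measurement groups."""
    state = _state_pools(model)
    seeds = set()
    for g in groups:
        if g.pool not in state:
            continue  # substrate fragments are read off the input mixture
        if representation == "cumomer":
            n = len(g.atoms)
            for sub in range(1, 2 ** n):
                mask = _mask_of([g.atoms[i] for i in range(n) if sub >> i & 1])
                seeds.add((g.pool, mask))
        else:
            seeds.add((g.pool, tuple(g.atoms)))
    return seeds


def _reachable(model: NetworkModel, seeds: set, representation: str) -> set:
    """Backward closure of ``seeds`` through the atom transitions."""
    state = _state_pools(model)
    transitions = model.transitions()
    needed = set(seeds)
    frontier = list(seeds)
    while frontier:
        pool, key = frontier.pop()
        atoms = _atoms_of(key) if representation == "cumomer" else key
        for t in transitions:
            for j, (pname, _) in enumerate(t.products):
                if pname != pool:
                    continue
                for ep, sub in _trace_sources(t, j, atoms):
                    if ep not in state:
                        continue
                    skey = _mask_of(sub) if representation == "cumomer" else sub
                    if (ep, skey) not in needed:
                        needed.add((ep, skey))
                        frontier.append((ep, skey))
    return needed


def _all_keys(model: NetworkModel, representation: str) -> set:
    keys = set()
    for p in model.pools:
        if p.name not in _state_pools(model):
            continue
        for mask in range(1, 2 ** p.n_atoms):
            if representation == "cumomer":
                keys.add((p.name, mask))
            else:
                keys.add((p.name, _atoms_of(mask)))
    return keys


def _full_count(model: NetworkModel, representation: str) -> int:
    total = 0
    for p in model.pools:
        if p.name not in _state_pools(model):
            continue
        n = p.n_atoms
        if representation == "cumomer":
            total += 2 ** n - 1
        else:
            total += sum(comb(n, s) * (s + 1) for s in range(1, n + 1))
    return total


def _build(
    model: NetworkModel,
    groups: Sequence[MsGroup] | None,
    representation: str,
    reduce: bool,
) -> tuple[CascadeSystem, ReductionReport]:
    if groups is None:
        groups = model.measurements.groups
    state = _state_pools(model)
    for g in groups:
        model.pool(g.pool)  # raises on unknown pool

    if reduce:
        needed = _reachable(model, _seed_keys(model, groups, representation), representation)
    else:
        needed = _all_keys(model, representation)

    def weight(key) -> int:
        return key.bit_count() if representation == "cumomer" else len(key)

    max_k = max((weight(k) for _, k in needed), default=0)
    pool_order = {p.name: i for i, p in enumerate(model.pools)}
    levels: list[Level] = []
    var_index: dict = {}
    for k in range(1, max_k + 1):
        vars_k = sorted(
            (pk for pk in needed if weight(pk[1]) == k),
            key=lambda pk: (pool_order[pk[0]], pk[1]),
        )
        variables = [
            Cumomer(p, key) if representation == "cumomer" else Emu(p, key)
            for p, key in vars_k
        ]
        for i, (p, key) in enumerate(vars_k):
            var_index[(p, key)] = (k, i)
        levels.append(Level(k=k, variables=variables))

    transitions = model.transitions()
    substrates = {p.name for p in model.pools if p.is_substrate}

    for lev in levels:
        for i, v in enumerate(lev.variables):
            pool = v.pool
            atoms = v.atoms
            # consumption: every transition consuming the pool drains all
            # of its labeling variables proportionally
            for t in transitions:
                cnt = sum(1 for ep, _ in t.educts if ep == pool)
                if cnt:
                    lev.a_terms.append(ATerm(i, i, (t.rate, t.reaction), float(cnt)))
            # production
            for t in transitions:
                for j, (pname, _) in enumerate(t.products):
                    if pname != pool:
                        continue
                    refs: list[Factor] = []
                    for ep, sub in _trace_sources(t, j, atoms):
                        if ep in substrates:
                            refs.append(("in", ep, sub))
                        else:
                            skey = _mask_of(sub) if representation == "cumomer" else sub
                            lk, idx = var_index[(ep, skey)]
                            refs.append(("st", lk, idx))
                    if len(refs) == 1 and refs[0][0] == "st" and refs[0][1] == lev.k:
                        lev.a_terms.append(
                            ATerm(i, refs[0][2], (t.rate, t.reaction), -1.0)
                        )
                    else:
                        lev.b_terms.append(BTerm(i, (t.rate, t.reaction), tuple(refs)))

    system = CascadeSystem(
        representation=representation, model=model, levels=levels, var_index=var_index
    )
    report = ReductionReport(
        representation=representation,
        full_variables=_full_count(model, representation),
        essential_variables=system.n_state_vars,
        per_level_sizes=system.per_level_sizes(),
        scalar_unknowns=system.n_state_scalars,
        reason="essential variables = backward reachability from measured fragments",
    )
    return system, report


def build_cumomer_system(
    model: NetworkModel, groups: Sequence[MsGroup] | None = None, reduce: bool = True
) -> tuple[CascadeSystem, ReductionReport]:
    """Essential-cumomer cascade for the given measurement groups.

    With ``reduce=False`` every cumomer of every non-substrate pool is
    retained (the unreduced reference system).
    """
    return _build(model, groups, "cumomer", reduce)


def build_emu_system(
    model: NetworkModel, groups: Sequence[MsGroup] | None = None, reduce: bool = True
) -> tuple[CascadeSystem, ReductionReport]:
    """EMU system obtained by backward decomposition from measured fragments."""
    return _build(model, groups, "emu", reduce)


def choose_representation(
    model: NetworkModel,
    groups: Sequence[MsGroup] | None = None,
    override: str | None = None,
) -> tuple[str, ReductionReport]:
    """Pick the representation with fewer scalar state unknowns.

    The scalar count (cumomer: number of state cumomers; EMU: sum of
    MID lengths) is the documented proxy for maximizing the reduction;
    ties go to cumomers, whose source terms are plain products.  An
    ``override`` of ``'cumomer'`` or ``'emu'`` wins unconditionally.
    """
    _, rep_c = build_cumomer_system(model, groups)
    _, rep_e = build_emu_system(model, groups)
    if override is not None:
        if override not in ("cumomer", "emu"):
            raise SemanticError(f"unknown representation {override!r}")
        chosen = override
        reason = "user override"
    elif rep_e.scalar_unknowns < rep_c.scalar_unknowns:
        chosen = "emu"
        reason = (
            f"emu has fewer scalar unknowns ({rep_e.scalar_unknowns} < "
            f"{rep_c.scalar_unknowns}); scalar-count proxy heuristic"
        )
    else:
        chosen = "cumomer"
        reason = (
            f"cumomer scalar unknowns {rep_c.scalar_unknowns} <= emu "
            f"{rep_e.scalar_unknowns}; ties prefer cumomer (scalar-count proxy heuristic)"
        )
    report = rep_c if chosen == "cumomer" else rep_e
    report.reason = reason
    return chosen, report
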