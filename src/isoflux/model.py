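"""Domain model for atom-mapped metabolic networks.

A :class:`NetworkModel` bundles everything a labeling simulation needs:
metabolite pools with traceable-atom counts, reactions with letter-coded
atom transitions, linear flux constraints, input substrate labeling
mixtures and the mass-spectrometric measurement configuration.

Atom maps use the compact letter convention: each educt atom is assigned a
lowercase letter (``cfg="ab"`` for a two-carbon educt) and every product
letter refers back to exactly one educt letter, so atoms are conserved by
construction.  Atom indices are 1-based in files and user-facing strings
and 0-based in memory; the parser/writer is the only place the conversion
happens.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Pool",
    "Reaction",
    "Transition",
    "InputMixture",
    "MsGroup",
    "Experiment",
    "MeasurementConfig",
    "LinearConstraint",
    "NetworkModel",
    "Diagnostic",
    "ModelError",
    "SemanticError",
    "validate",
    "stoichiometric_matrix",
]


class ModelError(ValueError):
    """Base class for model construction and parsing failures."""


class SemanticError(ModelError):
    """A structurally well-formed input that violates model semantics.

    Carries the name of the offending element and, when known, the source
    line in the file it came from.
    """

    def __init__(self, message: str, element: str | None = None, line: int | None = None):
        self.element = element
        self.line = line
        prefix = ""
        if element is not None:
            prefix += f"[{element}"
            if line is not None:
                prefix += f", line {line}"
            prefix += "] "
        super().__init__(prefix + message)


@dataclass(frozen=True)
class Pool:
    """A metabolite pool with a number of traceable carbon atoms.

    ``n_atoms == 0`` marks an untraced cofactor: it participates in flux
    balances but carries no labeling state.
    """

    name: str
    n_atoms: int
    is_substrate: bool = False
    is_excreted: bool = False

    def __post_init__(self) -> None:
        if self.n_atoms < 0:
            raise ModelError(f"pool {self.name!r}: n_atoms must be >= 0")


@dataclass(frozen=True)
class Reaction:
    """An atom-mapped reaction.

    ``educts`` and ``products`` are ordered tuples of ``(pool_name, cfg)``
    where ``cfg`` is the letter string assigning one lowercase letter per
    atom.  A reaction may have no products (an efflux that leaves the
    modeled system).
    """

    name: str
    educts: tuple[tuple[str, str], ...]
    products: tuple[tuple[str, str], ...]
    bidirectional: bool = False

    def educt_pools(self) -> list[str]:
        return [p for p, _ in self.educts]

    def product_pools(self) -> list[str]:
        return [p for p, _ in self.products]


@dataclass(frozen=True)
class Transition:
    """A unidirectional atom transition derived from a reaction.

    Bidirectional reactions contribute two transitions: the forward one and
    the backward one with educts and products swapped.  ``rate`` names which
    rate coordinate of the reaction drives the transition.
    """

    reaction: str
    rate: str  # 'fwd' | 'bwd'
    educts: tuple[tuple[str, str], ...]
    products: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class InputMixture:
    """Labeling composition of a substrate pool.

    ``components`` maps binary labeling patterns (e.g. ``"10"``: first atom
    13C, second 12C) to molar fractions that must sum to one.
    """

    pool: str
    components: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.components)
        if abs(total - 1.0) > 1e-9:
            raise SemanticError(
                f"input mixture for {self.pool!r}: fractions sum to {total}, not 1",
                element=f"input {self.pool}",
            )

    def cumomer_value(self, mask: int) -> float:
        """Probability that every atom in ``mask`` (bitset, bit i = atom i) is labeled."""
        val = 0.0
        for pattern, frac in self.components:
            pat = _pattern_to_mask(pattern)
            if pat & mask == mask:
                val += frac
        return val

    def mid(self, atoms: Sequence[int]) -> np.ndarray:
        """Mass-isotopomer distribution of the fragment over ``atoms`` (0-based)."""
        out = np.zeros(len(atoms) + 1)
        for pattern, frac in self.components:
            shift = sum(1 for a in atoms if pattern[a] == "1")
            out[shift] += frac
        return out


def _pattern_to_mask(pattern: str) -> int:
    mask = 0
    for i, c in enumerate(pattern):
        if c == "1":
            mask |= 1 << i
    return mask


@dataclass(frozen=True)
class MsGroup:
    """A mass-spectrometric measurement group (fragment MID).

    ``atoms`` are 0-based atom indices of the measured fragment, strictly
    increasing.  ``timepoints`` is a tuple of sampling times, or ``None``
    for an isotopically stationary measurement (the t=inf marker).  ``sd``
    holds one standard deviation per mass shift (length ``len(atoms)+1``).
    """

    id: str
    pool: str
    atoms: tuple[int, ...]
    timepoints: tuple[float, ...] | None
    sd: tuple[float, ...]

    @property
    def stationary(self) -> bool:
        return self.timepoints is None

    @property
    def n_shifts(self) -> int:
        return len(self.atoms) + 1


@dataclass(frozen=True)
class Experiment:
    """One isotope labeling experiment: an input mixture set plus a group subset."""

    id: str
    inputs: tuple[InputMixture, ...]
    group_ids: tuple[str, ...]

    def mixture(self, pool: str) -> InputMixture:
        for mix in self.inputs:
            if mix.pool == pool:
                return mix
        raise KeyError(f"experiment {self.id!r} has no input mixture for pool {pool!r}")


@dataclass(frozen=True)
class MeasurementConfig:
    groups: tuple[MsGroup, ...]
    experiments: tuple[Experiment, ...]

    def group(self, gid: str) -> MsGroup:
        for g in self.groups:
            if g.id == gid:
                return g
        raise KeyError(f"no measurement group {gid!r}")

    def experiment(self, eid: str) -> Experiment:
        for e in self.experiments:
            if e.id == eid:
                return e
        raise KeyError(f"no experiment {eid!r}")


@dataclass(frozen=True)
class LinearConstraint:
    """A linear equality  sum_j coeffs[j] * net_j = rhs  on net fluxes."""

    coeffs: Mapping[str, float]
    rhs: float


@dataclass
class NetworkModel:
    """A complete atom-mapped network with constraints and measurements.

    Bounds are kept separately for the net and exchange coordinates; a
    missing entry means the default bound (net: free for bidirectional
    reactions, ``[0, inf)`` for irreversible ones; exchange: ``[0, inf)``).
    """

    name: str
    pools: tuple[Pool, ...]
    reactions: tuple[Reaction, ...]
    equalities: tuple[LinearConstraint, ...] = ()
    net_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    xch_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    measurements: MeasurementConfig = field(
        default_factory=lambda: MeasurementConfig(groups=(), experiments=())
    )

    # -- lookups ---------------------------------------------------------
    def pool(self, name: str) -> Pool:
        try:
            return self._pool_index[name]
        except AttributeError:
            self._pool_index = {p.name: p for p in self.pools}
            return self._pool_index[name]

    def reaction(self, name: str) -> Reaction:
        for r in self.reactions:
            if r.name == name:
                return r
        raise KeyError(f"no reaction {name!r}")

    def reaction_index(self, name: str) -> int:
        for i, r in enumerate(self.reactions):
            if r.name == name:
                return i
        raise KeyError(f"no reaction {name!r}")

    @property
    def balanced_pools(self) -> list[Pool]:
        """Pools subject to a steady-state flux balance."""
        return [p for p in self.pools if not (p.is_substrate or p.is_excreted)]

    def net_bound(self, name: str) -> tuple[float, float]:
        if name in self.net_bounds:
            return self.net_bounds[name]
        r = self.reaction(name)
        return (-np.inf, np.inf) if r.bidirectional else (0.0, np.inf)

    def xch_bound(self, name: str) -> tuple[float, float]:
        if name in self.xch_bounds:
            return self.xch_bounds[name]
        return (0.0, np.inf)

    def transitions(self) -> list[Transition]:
        """Unidirectional atom transitions (bidirectional reactions give two)."""
        out: list[Transition] = []
        for r in self.reactions:
            out.append(Transition(r.name, "fwd", r.educts, r.products))
            if r.bidirectional:
                out.append(Transition(r.name, "bwd", r.products, r.educts))
        return out

    def with_equalities(self, extra: Iterable[LinearConstraint]) -> "NetworkModel":
        return replace(self, equalities=self.equalities + tuple(extra))


@dataclass(frozen=True)
class Diagnostic:
    severity: str  # 'error' | 'warning'
    category: str  # 'semantic' | 'logic' | 'numeric' | 'syntactic'
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.severity} ({self.category}): {self.message}"


def _check_reaction_atoms(model: NetworkModel, r: Reaction) -> list[Diagnostic]:
    diags: list[Diagnostic] = []
    seen: dict[str, int] = {}
    pool_names = {p.name for p in model.pools}
    for pname, cfg in r.educts + r.products:
        if pname not in pool_names:
            diags.append(
                Diagnostic("error", "semantic", f"reaction {r.name!r}: unknown pool {pname!r}")
            )
            return diags
        if len(cfg) != model.pool(pname).n_atoms:
            diags.append(
                Diagnostic(
                    "error",
                    "semantic",
                    f"reaction {r.name!r}: cfg {cfg!r} has {len(cfg)} letters "
                    f"but pool {pname!r} has {model.pool(pname).n_atoms} atoms",
                )
            )
    educt_letters: list[str] = []
    for _, cfg in r.educts:
        educt_letters.extend(cfg)
    if len(set(educt_letters)) != len(educt_letters):
        dup = sorted({c for c in educt_letters if educt_letters.count(c) > 1})
        diags.append(
            Diagnostic(
                "error",
                "semantic",
                f"reaction {r.name!r}: duplicate educt atom letter(s) {','.join(dup)}",
            )
        )
    product_letters: list[str] = []
    for _, cfg in r.products:
        product_letters.extend(cfg)
    for c in product_letters:
        if c not in educt_letters:
            diags.append(
                Diagnostic("error", "semantic", f"reaction {r.name!r}: unbalanced atom {c}")
            )
    if len(set(product_letters)) != len(product_letters):
        dup = sorted({c for c in product_letters if product_letters.count(c) > 1})
        diags.append(
            Diagnostic(
                "error",
                "semantic",
                f"reaction {r.name!r}: atom letter(s) {','.join(dup)} used in several products",
            )
        )
    return diags


def validate(model: NetworkModel) -> list[Diagnostic]:
    """Check all model invariants; an empty list means the model is valid.

    Diagnostics carry a severity (errors make the model unusable, warnings
    do not) and a category so callers can route them.
    """
    diags: list[Diagnostic] = []
    names = [p.name for p in model.pools]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        diags.append(Diagnostic("error", "semantic", f"duplicate pool name(s): {','.join(dup)}"))
        return diags

    rnames = [r.name for r in model.reactions]
    if len(set(rnames)) != len(rnames):
        dup = sorted({n for n in rnames if rnames.count(n) > 1})
        diags.append(
            Diagnostic("error", "semantic", f"duplicate reaction name(s): {','.join(dup)}")
        )

    for r in model.reactions:
        diags.extend(_check_reaction_atoms(model, r))

    # production / consumption coverage of balanced pools
    produced: set[str] = set()
    consumed: set[str] = set()
    for r in model.reactions:
        consumed.update(r.educt_pools())
        produced.update(r.product_pools())
        if r.bidirectional:
            consumed.update(r.product_pools())
            produced.update(r.educt_pools())
    for p in model.balanced_pools:
        if p.name not in produced:
            diags.append(
                Diagnostic("error", "logic", f"pool {p.name!r} is consumed but never produced")
                if p.name in consumed
                else Diagnostic("error", "logic", f"pool {p.name!r} is never produced")
            )
        if p.name not in consumed:
            diags.append(Diagnostic("error", "logic", f"pool {p.name!r} is never consumed"))

    # constraints reference known reactions
    for eq in model.equalities:
        for rn in eq.coeffs:
            if rn not in rnames:
                diags.append(
                    Diagnostic("error", "semantic", f"constraint references unknown flux {rn!r}")
                )
    for rn in list(model.net_bounds) + list(model.xch_bounds):
        if rn not in rnames:
            diags.append(
                Diagnostic("error", "semantic", f"bound references unknown flux {rn!r}")
            )

    for r in model.reactions:
        if r.bidirectional:
            lo, hi = model.xch_bound(r.name)
            if lo == 0.0 and hi == 0.0:
                diags.append(
                    Diagnostic(
                        "warning",
                        "logic",
                        f"reaction {r.name!r}: exchange fixed to zero; treated as irreversible",
                    )
                )
        else:
            if r.name in model.xch_bounds and model.xch_bounds[r.name] != (0.0, 0.0):
                diags.append(
                    Diagnostic(
                        "error",
                        "semantic",
                        f"irreversible reaction {r.name!r} has nonzero exchange bounds",
                    )
                )

    # measurement configuration
    pool_by_name = {p.name: p for p in model.pools}
    for g in model.measurements.groups:
        if g.pool not in pool_by_name:
            diags.append(
                Diagnostic("error", "semantic", f"group {g.id!r}: unknown pool {g.pool!r}")
            )
            continue
        n = pool_by_name[g.pool].n_atoms
        if not g.atoms:
            diags.append(Diagnostic("error", "semantic", f"group {g.id!r}: empty atom set"))
        elif any(a < 0 or a >= n for a in g.atoms):
            diags.append(
                Diagnostic(
                    "error",
                    "semantic",
                    f"group {g.id!r}: atom index out of range for pool {g.pool!r}",
                )
            )
        elif any(b <= a for a, b in zip(g.atoms, g.atoms[1:])):
            diags.append(
                Diagnostic("error", "semantic", f"group {g.id!r}: atoms not strictly increasing")
            )
        if any(s <= 0 for s in g.sd):
            diags.append(Diagnostic("error", "semantic", f"group {g.id!r}: sd must be > 0"))
        if len(g.sd) != g.n_shifts:
            diags.append(
                Diagnostic(
                    "error",
                    "semantic",
                    f"group {g.id!r}: {len(g.sd)} sd values for {g.n_shifts} mass shifts",
                )
            )
        if g.timepoints is not None and any(t < 0 for t in g.timepoints):
            diags.append(
                Diagnostic("error", "semantic", f"group {g.id!r}: negative timepoint")
            )
    for e in model.measurements.experiments:
        for gid in e.group_ids:
            try:
                model.measurements.group(gid)
            except KeyError:
                diags.append(
                    Diagnostic(
                        "error", "semantic", f"experiment {e.id!r}: unknown group {gid!r}"
                    )
                )
        for mix in e.inputs:
            if mix.pool not in pool_by_name:
                diags.append(
                    Diagnostic(
                        "error", "semantic", f"experiment {e.id!r}: unknown input pool {mix.pool!r}"
                    )
                )
            else:
                p = pool_by_name[mix.pool]
                if not p.is_substrate:
                    diags.append(
                        Diagnostic(
                            "error",
                            "semantic",
                            f"experiment {e.id!r}: input pool {mix.pool!r} is not a substrate",
                        )
                    )
                for pattern, _ in mix.components:
                    if len(pattern) != p.n_atoms or any(c not in "01" for c in pattern):
                        diags.append(
                            Diagnostic(
                                "error",
                                "semantic",
                                f"experiment {e.id!r}: bad labeling pattern {pattern!r} "
                                f"for pool {mix.pool!r}",
                            )
                        )
    return diags


def assert_valid(model: NetworkModel) -> NetworkModel:
    """Raise :class:`SemanticError` on the first validation error."""
    for d in validate(model):
        if d.severity == "error":
            raise SemanticError(d.message)
    return model


def stoichiometric_matrix(model: NetworkModel) -> sp.csr_matrix:
    """Net stoichiometric matrix, balanced pools x reactions.

    Entry (i, j) is the number of times pool i appears among the products
    of reaction j minus the number of times it appears among the educts.
    Substrate and excreted pools carry no balance row.
    """
    rows = {p.name: i for i, p in enumerate(model.balanced_pools)}
    mat = sp.lil_matrix((len(rows), len(model.reactions)))
    for j, r in enumerate(model.reactions):
        for pname in r.product_pools():
            if pname in rows:
                mat[rows[pname], j] += 1
        for pname in r.educt_pools():
            if pname in rows:
                mat[rows[pname], j] -= 1
    return mat.tocsr()
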