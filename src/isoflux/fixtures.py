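"""Fixture network library and synthetic-data generation.

The fixtures are small, fully documented networks spanning the structural
motifs that matter for labeling simulation: linear transport, converging
mixing, branching with atom permutation, cleavage/condensation (with a
reversible condensation step), reversible exchange, widely spread pool
sizes (stiffness) and a deliberately non-identifiable parallel-route
network.  Each fixture ships as a FluxML-subset file plus the true
parameter values used to generate synthetic data.  All fixtures stay
below 12 traced atoms so the brute-force isotopomer oracle applies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np

from .fluxml import parse_fluxml
from .model import NetworkModel
from .observe import MeasuredData, SimulatedData, Simulator
from .steady import FluxState
from .transient import PoolSizes

__all__ = ["Fixture", "make_fixtures", "load_fixture", "make_synthetic_data"]


@dataclass
class Fixture:
    name: str
    model: NetworkModel
    true_net: dict[str, float]
    true_xch: dict[str, float]
    true_pools: dict[str, float]
    description: str

    @property
    def flux(self) -> FluxState:
        return FluxState.from_dict(self.model, self.true_net, self.true_xch)

    @property
    def pools(self) -> PoolSizes | None:
        return PoolSizes(sizes=dict(self.true_pools)) if self.true_pools else None


_TRUTH: dict[str, tuple[dict, dict, dict, str]] = {
    "linchain": (
        {"v1": 1.0, "v2": 1.0, "v3": 1.0},
        {},
        {"B": 1.0, "C": 1.5},
        "three-pool linear chain A->B->C->efflux with identity atom transport",
    ),
    "mix": (
        {"v1": 3.0, "v2": 1.0, "v3": 4.0},
        {},
        {"B": 2.0},
        "two labeled/unlabeled substrates converging on one pool (flux-weighted mixing)",
    ),
    "branch": (
        {"v1": 1.0, "v2": 0.7, "v3": 0.3, "v4": 0.7, "v5": 0.3, "v6": 1.0},
        {},
        {"B": 0.8, "C": 1.2, "D": 0.5, "E": 1.5},
        "branch and recombine; one branch swaps the two atoms, so the positional "
        "fragment E#M(1) identifies the split ratio (identifiable recovery fixture)",
    ),
    "cleave_condense": (
        {"v1": 1.0, "v2": 1.0, "v3": 1.0},
        {"v2": 0.4},
        {"B": 0.5, "C": 0.4, "D": 0.9},
        "cleavage A->B+C and reversible condensation B+C->D (MID convolution)",
    ),
    "reversible_loop": (
        {"v1": 1.0, "v2": 1.0, "v3": 1.0},
        {"v2": 0.5},
        {"B": 1.0, "C": 2.0},
        "reversible B<->C exchange; labeling dynamics depend on the exchange flux",
    ),
    "stiff_pools": (
        {"v1": 1.0, "v2": 1.0, "v3": 1.0, "v4": 1.0},
        {},
        {"B": 1e-3, "C": 10.0, "D": 0.1},
        "pool sizes spanning 4 orders of magnitude (stiff washin cascade)",
    ),
    "degenerate_parallel": (
        {"v1": 0.5, "v2": 0.5, "v3": 1.0},
        {},
        {"B": 1.0},
        "two identical parallel routes; only their sum is identifiable",
    ),
    "washin1": (
        {"v1": 1.0, "v2": 1.0},
        {},
        {"P": 2.0},
        "single-pool washin; closed form x(t) = 1 - exp(-v t / X)",
    ),
    "washin2": (
        {"v1": 1.0, "v2": 1.0, "v3": 1.0},
        {},
        {"P1": 2.0, "P2": 2.0},
        "two-pool cascade with equal time constants; "
        "x2(t) = 1 - exp(-t/tau) (1 + t/tau), tau = X/v",
    ),
}


def load_fixture(name: str) -> Fixture:
    if name not in _TRUTH:
        raise KeyError(f"no fixture {name!r}; known: {sorted(_TRUTH)}")
    ref = resources.files("isoflux.data").joinpath(f"{name}.fml")
    with resources.as_file(ref) as path:
        model = parse_fluxml(path)
    net, xch, pools, desc = _TRUTH[name]
    return Fixture(
        name=name, model=model, true_net=net, true_xch=xch, true_pools=pools, description=desc
    )


def make_fixtures() -> dict[str, Fixture]:
    """The full fixture registry, keyed by name."""
    return {name: load_fixture(name) for name in _TRUTH}


def make_synthetic_data(
    fixture: Fixture,
    flux: FluxState | None = None,
    pools: PoolSizes | None = None,
    noise_sd: float | None = None,
    seed: int = 0,
    timepoints: list[float] | None = None,
    representation: str | None = None,
) -> tuple[MeasuredData, SimulatedData]:
    """Simulate a fixture at its true parameters and add Gaussian noise.

    ``noise_sd`` overrides the per-group standard deviations (None keeps
    them); noisy MIDs are clamped to [0, 1] without renormalizing, so
    noisy data need not sum to one, exactly as measured spectra do not.
    Returns ``(noisy_data, noise_free_truth)``.
    """
    model = fixture.model
    if timepoints is not None:
        groups = tuple(
            g if g.stationary else replace(g, timepoints=tuple(timepoints))
            for g in model.measurements.groups
        )
        model = replace(model, measurements=replace(model.measurements, groups=groups))
    sim = Simulator(model, representation)
    flux = flux if flux is not None else fixture.flux
    pools = pools if pools is not None else fixture.pools
    truth = sim.simulate(flux, pools)
    rng = np.random.default_rng(seed)
    tab = truth.table.copy()
    sds = np.empty(len(tab))
    for i, row in enumerate(tab.itertuples()):
        g = model.measurements.group(row.group)
        sds[i] = noise_sd if noise_sd is not None else g.sd[int(row.mass_shift)]
    noisy = tab.value.to_numpy() + rng.normal(0.0, sds)
    tab["value"] = np.clip(noisy, 0.0, 1.0)
    tab["sd"] = sds
    return MeasuredData(table=tab), truth
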