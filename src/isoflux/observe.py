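"""Mapping labeling states to measured quantities and residuals.

Simulated measurement groups are fragment MIDs.  EMU states carry MIDs
directly; cumomer states are converted per group by the inclusion-
exclusion transform restricted to the measured atom subset (built once
per fragment size).  Measured data live in tidy tables
``experiment, group, time, mass_shift, value, sd`` with ``time = inf``
marking isotopically stationary values.  Residuals are variance-weighted
differences ``(sim - meas) / sd``; MIDs are compared as normalized
fractions (no fitted scale factors), and mass shifts absent from the data
are treated as unmeasured and dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import ModelError, MsGroup, NetworkModel
from .statespace import build_cumomer_system, build_emu_system, choose_representation
from .steady import FluxState, LabelingState, Parameter, StationarySolver
from .transient import PoolSizes, Trajectory, inst_sensitivities, solve_inst, solve_inst_sdirk

__all__ = [
    "SimulatedData",
    "MeasuredData",
    "ResidualVector",
    "mid_transform",
    "group_mid",
    "simulate_measurements",
    "residuals",
    "residual_jacobian",
    "Simulator",
]

_COLUMNS = ["experiment", "group", "time", "mass_shift", "value"]


@lru_cache(maxsize=None)
def mid_transform(size: int) -> np.ndarray:
    """Cumomer-to-MID inclusion-exclusion transform for a fragment.

    Returns T of shape ``(size+1, 2**size)`` with ``MID = T @ x`` where
    ``x[j]`` is the cumomer value of the mask encoded by the bits of j
    (``x[0] = 1``, the weight-0 cumomer).  Only the mask weight enters:
    ``T[k, j] = (-1)**(w-k) * C(w, k)`` for ``w = popcount(j) >= k``.
    """
    T = np.zeros((size + 1, 2**size))
    for j in range(2**size):
        w = bin(j).count("1")
        for k in range(w + 1):
            T[k, j] = (-1.0) ** (w - k) * comb(w, k)
    return T


def group_mid(state: LabelingState, group: MsGroup) -> np.ndarray:
    """Fragment MID of one measurement group from a labeling state."""
    if state.representation == "emu":
        return np.asarray(state.emu_mid(group.pool, group.atoms), dtype=float)
    s = len(group.atoms)
    xs = np.empty(2**s)
    for j in range(2**s):
        mask = 0
        for i in range(s):
            if j >> i & 1:
                mask |= 1 << group.atoms[i]
        xs[j] = state.cumomer(group.pool, mask)
    return mid_transform(s) @ xs


@dataclass
class SimulatedData:
    """Simulated group MIDs in tidy form (one row per mass shift)."""

    table: pd.DataFrame

    def to_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        out["sd"] = ""
        out.to_csv(path, index=False)

    def mid(self, experiment: str, group: str, time: float) -> np.ndarray:
        sel = self.table[
            (self.table.experiment == experiment)
            & (self.table.group == group)
            & (self.table.time == time)
        ].sort_values("mass_shift")
        return sel.value.to_numpy()


@dataclass
class MeasuredData:
    """Measured group MIDs with per-value standard deviations."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS + ["sd"] if c not in self.table.columns]
        if missing:
            raise ModelError(f"measured data table is missing column(s) {missing}")
        if (self.table.sd <= 0).any():
            raise ModelError("measured data: sd must be > 0")

    @classmethod
    def read_csv(cls, path: str | Path) -> "MeasuredData":
        tab = pd.read_csv(path)
        missing = [c for c in _COLUMNS + ["sd"] if c not in tab.columns]
        if missing:
            raise ModelError(f"{path}: missing column(s) {missing}")
        tab["time"] = tab["time"].astype(float)  # 'inf' parses to np.inf
        return cls(table=tab[_COLUMNS + ["sd"]])

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def n_values(self) -> int:
        return len(self.table)


@dataclass
class ResidualVector:
    """Stacked variance-weighted residuals with an index back to their origin."""

    values: np.ndarray
    index: pd.DataFrame  # experiment, group, time, mass_shift, sim, meas, sd

    @property
    def ssr(self) -> float:
        return float(self.values @ self.values)

    def __len__(self) -> int:
        return len(self.values)


def residuals(sim: SimulatedData, meas: MeasuredData) -> ResidualVector:
    """Variance-weighted residual vector ``(sim - meas)/sd`` and its index map.

    Every measured value must have a simulated counterpart; simulated
    values without a measurement are ignored.
    """
    merged = meas.table.merge(
        sim.table.rename(columns={"value": "sim"}),
        on=["experiment", "group", "time", "mass_shift"],
        how="left",
    )
    if merged.sim.isna().any():
        row = merged[merged.sim.isna()].iloc[0]
        raise ModelError(
            f"no simulated value for group {row.group!r} at time {row.time} "
            f"(experiment {row.experiment!r}, mass shift {int(row.mass_shift)})"
        )
    vals = ((merged.sim - merged.value) / merged.sd).to_numpy()
    index = merged.rename(columns={"value": "meas"})[
        ["experiment", "group", "time", "mass_shift", "sim", "meas", "sd"]
    ]
    return ResidualVector(values=vals, index=index)


def residual_jacobian(
    sens_sims: Sequence[SimulatedData], meas: MeasuredData
) -> np.ndarray:
    """Jacobian d r_i / d p_j of the residuals w.r.t. the parameter list.

    ``sens_sims`` holds one simulated-derivative table per parameter, in
    the same layout as the simulation itself.
    """
    cols = []
    for ds in sens_sims:
        merged = meas.table.merge(
            ds.table.rename(columns={"value": "dsim"}),
            on=["experiment", "group", "time", "mass_shift"],
            how="left",
        )
        if merged.dsim.isna().any():
            raise ModelError("sensitivity table does not cover the measured values")
        cols.append((merged.dsim / merged.sd).to_numpy())
    return np.column_stack(cols) if cols else np.zeros((meas.n_values, 0))


def _rows(eid: str, gid: str, time: float, mid: np.ndarray) -> list[dict]:
    return [
        {"experiment": eid, "group": gid, "time": time, "mass_shift": k, "value": float(v)}
        for k, v in enumerate(mid)
    ]


def simulate_measurements(
    state_or_trajectory: LabelingState | Trajectory,
    model: NetworkModel,
    experiment_id: str,
    groups: Sequence[MsGroup] | None = None,
) -> SimulatedData:
    """Evaluate measurement groups against one labeling state or trajectory.

    Stationary groups require a stationary :class:`LabelingState`; groups
    with timepoints require a :class:`Trajectory` covering those times.
    """
    e = model.measurements.experiment(experiment_id)
    if groups is None:
        groups = [model.measurements.group(g) for g in e.group_ids]
    rows: list[dict] = []
    for g in groups:
        if isinstance(state_or_trajectory, Trajectory):
            if g.stationary:
                raise ModelError(f"group {g.id!r} is stationary; needs a stationary state")
            for t in g.timepoints:
                rows += _rows(e.id, g.id, t, group_mid(state_or_trajectory.state_at(t), g))
        else:
            time = np.inf if g.stationary else 0.0
            rows += _rows(e.id, g.id, time, group_mid(state_or_trajectory, g))
    return SimulatedData(table=pd.DataFrame(rows, columns=_COLUMNS))


class Simulator:
    """The simulator object: dimension-reduced system plus measurement access.

    Built once per model (and optional representation override), it
    simulates all experiments of the measurement configuration for a
    given flux state (and pool sizes, when transient groups are present),
    and provides residuals and parameter sensitivities in the same
    layout.
    """

    def __init__(
        self,
        model: NetworkModel,
        representation: str | None = None,
        rtol: float = 1e-8,
        atol: float = 1e-10,
        integrator: str = "BDF",
    ):
        self.model = model
        chosen, report = choose_representation(model, override=representation)
        build = build_cumomer_system if chosen == "cumomer" else build_emu_system
        self.system, _ = build(model)
        self.report = report
        self.rtol, self.atol = rtol, atol
        self.integrator = integrator

    @property
    def representation(self) -> str:
        return self.system.representation

    def _experiment_groups(self, e) -> tuple[list[MsGroup], list[MsGroup]]:
        groups = [self.model.measurements.group(g) for g in e.group_ids]
        return (
            [g for g in groups if g.stationary],
            [g for g in groups if not g.stationary],
        )

    def needs_pool_sizes(self) -> bool:
        return any(
            not self.model.measurements.group(g).stationary
            for e in self.model.measurements.experiments
            for g in e.group_ids
        )

    def simulate(self, flux: FluxState, pools: PoolSizes | None = None) -> SimulatedData:
        rows: list[dict] = []
        solver = StationarySolver(self.system, flux)  # LU shared across experiments
        for e in self.model.measurements.experiments:
            stat_groups, trans_groups = self._experiment_groups(e)
            if stat_groups:
                state = solver.solve(e.inputs)
                for g in stat_groups:
                    rows += _rows(e.id, g.id, np.inf, group_mid(state, g))
            if trans_groups:
                if pools is None:
                    raise ModelError("transient measurement groups require pool sizes")
                times = sorted({t for g in trans_groups for t in g.timepoints})
                integrate = solve_inst if self.integrator == "BDF" else solve_inst_sdirk
                traj = integrate(
                    self.system, flux, pools, e.inputs, times, rtol=self.rtol, atol=self.atol
                )
                for g in trans_groups:
                    for t in g.timepoints:
                        rows += _rows(e.id, g.id, t, group_mid(traj.state_at(t), g))
        return SimulatedData(table=pd.DataFrame(rows, columns=_COLUMNS))

    def simulate_with_sensitivities(
        self,
        flux: FluxState,
        parameters: Sequence[Parameter],
        pools: PoolSizes | None = None,
    ) -> tuple[SimulatedData, list[SimulatedData]]:
        """Simulated data plus one derivative table per parameter."""
        rows: list[dict] = []
        drows: list[list[dict]] = [[] for _ in parameters]
        solver = StationarySolver(self.system, flux)
        for e in self.model.measurements.experiments:
            stat_groups, trans_groups = self._experiment_groups(e)
            if stat_groups:
                state = solver.solve(e.inputs)
                dstates = solver.sensitivities(state, parameters)
                for g in stat_groups:
                    rows += _rows(e.id, g.id, np.inf, group_mid(state, g))
                    for p, ds in enumerate(dstates):
                        drows[p] += _rows(e.id, g.id, np.inf, group_mid(ds, g))
            if trans_groups:
                if pools is None:
                    raise ModelError("transient measurement groups require pool sizes")
                times = sorted({t for g in trans_groups for t in g.timepoints})
                traj, sens = inst_sensitivities(
                    self.system,
                    flux,
                    pools,
                    e.inputs,
                    times,
                    parameters,
                    rtol=self.rtol,
                    atol=self.atol,
                    method=self.integrator,
                )
                for g in trans_groups:
                    for t in g.timepoints:
                        rows += _rows(e.id, g.id, t, group_mid(traj.state_at(t), g))
                        for p, st in enumerate(sens):
                            drows[p] += _rows(e.id, g.id, t, group_mid(st.state_at(t), g))
        sim = SimulatedData(table=pd.DataFrame(rows, columns=_COLUMNS))
        dsims = [SimulatedData(table=pd.DataFrame(dr, columns=_COLUMNS)) for dr in drows]
        return sim, dsims

    def residuals(
        self, flux: FluxState, meas: MeasuredData, pools: PoolSizes | None = None
    ) -> ResidualVector:
        return residuals(self.simulate(flux, pools), meas)
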