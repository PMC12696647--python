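"""High-level modeling interface: build a model from data, fit, summarize.

:class:`FluxModel` couples a metabolic network (with its measurement
configuration) to measured labeling data; ``fit()`` returns a
:class:`FluxResults` carrying the estimated free parameters, their
linearized standard errors, diagnostics and a ``summary()`` table, in the
style of the classic statistical modeling packages.  Posterior sampling
and plotting hang off the same two objects.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import infer
from .fluxml import parse_fluxml
from .jsonio import parse_json_model
from .model import NetworkModel
from .observe import MeasuredData, SimulatedData, Simulator
from .steady import FluxState
from .transient import PoolSizes

__all__ = ["FluxModel", "FluxResults"]


class FluxModel:
    """A 13C-MFA estimation problem: network + atom maps + labeling data."""

    def __init__(
        self,
        network: NetworkModel,
        data: MeasuredData | None = None,
        representation: str | None = None,
        rtol: float = 1e-8,
        atol: float = 1e-10,
        pool_bounds: tuple[float, float] = (1e-2, 1e2),
    ):
        self.network = network
        self.data = data
        self.pool_bounds = pool_bounds
        self.simulator = Simulator(network, representation, rtol=rtol, atol=atol)

    @classmethod
    def from_files(
        cls, model_path: str | Path, data_path: str | Path | None = None, **kwargs
    ) -> "FluxModel":
        model_path = Path(model_path)
        parse = parse_json_model if model_path.suffix == ".json" else parse_fluxml
        network = parse(model_path)
        data = MeasuredData.read_csv(data_path) if data_path is not None else None
        return cls(network, data, **kwargs)

    # -- simulation ------------------------------------------------------
    def simulate(
        self,
        net: Mapping[str, float] | FluxState,
        xch: Mapping[str, float] | None = None,
        pools: Mapping[str, float] | PoolSizes | None = None,
    ) -> SimulatedData:
        flux = net if isinstance(net, FluxState) else FluxState.from_dict(self.network, net, xch)
        if pools is not None and not isinstance(pools, PoolSizes):
            pools = PoolSizes(sizes=dict(pools))
        return self.simulator.simulate(flux, pools)

    # -- estimation ------------------------------------------------------
    def fit(self, n_starts: int = 5, seed: int = 0, **options) -> "FluxResults":
        if self.data is None:
            raise ValueError("fit() requires measured data")
        res = infer.fit(
            self.network,
            self.data,
            n_starts=n_starts,
            seed=seed,
            simulator=self.simulator,
            pool_bounds=self.pool_bounds,
            **options,
        )
        return FluxResults(self, res)

    def sample(
        self, n_draws: int = 2000, seed: int = 0, n_chains: int = 1, **options
    ) -> infer.PosteriorSample:
        return infer.sample_posterior(
            self.network,
            self.data,
            n_draws=n_draws,
            seed=seed,
            n_chains=n_chains,
            simulator=self.simulator,
            pool_bounds=self.pool_bounds,
            **options,
        )


class FluxResults:
    """Estimation results: parameters, uncertainties, diagnostics."""

    def __init__(self, model: FluxModel, fitres: infer.FitResult):
        self.model = model
        self._fit = fitres

    # -- parameter views -------------------------------------------------
    @property
    def params(self) -> pd.Series:
        return pd.Series(self._fit.theta, index=list(self._fit.names), name="estimate")

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self._fit.bse(), index=list(self._fit.names), name="std err")

    @property
    def ssr(self) -> float:
        return self._fit.ssr

    @property
    def history(self) -> list[dict]:
        return self._fit.history

    @property
    def fluxes(self) -> pd.DataFrame:
        flux = self._fit.flux
        return pd.DataFrame(
            {"net": flux.net, "xch": flux.xch, "fwd": flux.fwd, "bwd": flux.bwd},
            index=list(flux.reactions),
        )

    @property
    def pool_sizes(self) -> pd.Series | None:
        pools = self._fit.pools
        if pools is None:
            return None
        return pd.Series(pools.sizes, name="pool size")

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        rows = [infer.linearized_ci(self._fit, i, level) for i in range(len(self._fit.theta))]
        return pd.DataFrame(rows, index=list(self._fit.names), columns=["lower", "upper"])

    def sample_posterior(self, n_draws: int = 2000, seed: int = 0, n_chains: int = 1, **kw):
        return self.model.sample(n_draws=n_draws, seed=seed, n_chains=n_chains, **kw)

    def summary(self, level: float = 0.95) -> str:
        """Plain-text estimation summary (linearized uncertainties)."""
        ci = self.conf_int(level)
        n_meas = len(self._fit.residual.values)
        dof = n_meas - len(self._fit.theta)
        lines = [
            "13C-MFA least-squares estimation",
            "=" * 64,
            f"measurements: {n_meas}    free parameters: {len(self._fit.theta)}"
            f"    dof: {dof}",
            f"SSR: {self.ssr:.6g}    |grad|: {self._fit.grad_norm:.3g}    "
            f"starts converged: {sum(1 for e in self.history if e.get('converged'))}"
            f"/{len(self.history)}",
            "-" * 64,
            f"{'parameter':<16}{'estimate':>12}{'std err':>12}"
            f"{'[' + format(level, '.0%'):>12}{']':>10}",
        ]
        for name, est, se, (lo, hi) in zip(
            self._fit.names, self._fit.theta, self._fit.bse(), ci.itertuples(index=False)
        ):
            lines.append(f"{name:<16}{est:>12.5g}{se:>12.3g}{lo:>12.4g}{hi:>10.4g}")
        lines.append("=" * 64)
        lines.append("intervals are linearized (J'J pseudo-inverse); approximate.")
        return "\n".join(lines)

    # -- goodness of fit -------------------------------------------------
    def fitted_values(self) -> pd.DataFrame:
        return self._fit.residual.index

    def plot_fit(self, group: str | None = None, experiment: str | None = None):
        """Measured vs fitted values; one panel per measurement group."""
        import matplotlib.pyplot as plt

        tab = self._fit.residual.index
        if group is not None:
            tab = tab[tab.group == group]
        if experiment is not None:
            tab = tab[tab.experiment == experiment]
        keys = tab[["experiment", "group"]].drop_duplicates()
        fig, axes = plt.subplots(1, len(keys), figsize=(4 * len(keys), 3), squeeze=False)
        for ax, (_, key) in zip(axes.ravel(), keys.iterrows()):
            sel = tab[(tab.experiment == key.experiment) & (tab.group == key.group)]
            if np.isfinite(sel.time).any():
                for shift, sub in sel.groupby("mass_shift"):
                    ax.errorbar(sub.time, sub.meas, yerr=sub.sd, fmt="o", ms=3,
                                label=f"M+{int(shift)}")
                    ax.plot(sub.time, sub.sim, "-")
                ax.set_xlabel("time")
            else:
                ax.errorbar(sel.mass_shift, sel.meas, yerr=sel.sd, fmt="o", ms=4)
                ax.plot(sel.mass_shift, sel.sim, "s", mfc="none")
                ax.set_xlabel("mass shift")
            ax.set_title(f"{key.experiment}:{key.group}")
            ax.set_ylabel("fraction")
            if ax.get_legend_handles_labels()[1]:
                ax.legend(fontsize=7)
        fig.tight_layout()
        return fig
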