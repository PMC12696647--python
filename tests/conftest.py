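import numpy as np
import pytest

from isoflux.fixtures import Fixture, make_fixtures
from isoflux.observe import MeasuredData, Simulator


@pytest.fixture(scope="session")
def fixtures() -> dict[str, Fixture]:
    return make_fixtures()


def zero_noise_data(fixture: Fixture, representation: str | None = None) -> MeasuredData:
    """Exact simulated data at the fixture's true parameters, with group sds."""
    sim = Simulator(fixture.model, representation)
    tab = sim.simulate(fixture.flux, fixture.pools).table.copy()
    tab["sd"] = [
        fixture.model.measurements.group(r.group).sd[int(r.mass_shift)]
        for r in tab.itertuples()
    ]
    return MeasuredData(table=tab)


def assert_mid_distribution(mid: np.ndarray, atol_sum: float = 1e-8, atol_neg: float = 1e-9):
    mid = np.asarray(mid)
    assert np.all(mid >= -atol_neg), f"negative MID entry: {mid}"
    assert abs(mid.sum() - 1.0) <= atol_sum, f"MID sums to {mid.sum()}: {mid}"


def stationary_only(model):
    """Restrict a model's measurement configuration to its stationary groups."""
    from dataclasses import replace

    groups = tuple(g for g in model.measurements.groups if g.stationary)
    keep = {g.id for g in groups}
    exps = tuple(
        replace(e, group_ids=tuple(g for g in e.group_ids if g in keep))
        for e in model.measurements.experiments
    )
    exps = tuple(e for e in exps if e.group_ids)
    return replace(model, measurements=replace(model.measurements, groups=groups, experiments=exps))
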