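"""JSON dialect of the network model, mirroring :class:`NetworkModel` fields.

The JSON form is a single object::

    {"name": ..., "pools": [...], "reactions": [...], "equalities": [...],
     "net_bounds": {...}, "xch_bounds": {...}, "groups": [...],
     "experiments": [...]}

Atom indices are 1-based (as in FluxML); ``null`` stands for an infinite
bound; ``"times": "inf"`` marks a stationary group.  A model parsed from
this dialect compares deep-equal to the same model parsed from FluxML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .model import (
    Experiment,
    InputMixture,
    LinearConstraint,
    MeasurementConfig,
    ModelError,
    MsGroup,
    NetworkModel,
    Pool,
    Reaction,
    SemanticError,
    assert_valid,
)

__all__ = ["parse_json_model", "write_json", "model_to_dict", "model_from_dict"]


def _bound_out(b: tuple[float, float]) -> list:
    return [None if not np.isfinite(b[0]) else b[0], None if not np.isfinite(b[1]) else b[1]]


def _bound_in(b) -> tuple[float, float]:
    lo = -np.inf if b[0] is None else float(b[0])
    hi = np.inf if b[1] is None else float(b[1])
    return (lo, hi)


def model_to_dict(model: NetworkModel) -> dict:
    return {
        "name": model.name,
        "pools": [
            {
                "name": p.name,
                "atoms": p.n_atoms,
                "substrate": p.is_substrate,
                "excreted": p.is_excreted,
            }
            for p in model.pools
        ],
        "reactions": [
            {
                "name": r.name,
                "educts": [[p, c] for p, c in r.educts],
                "products": [[p, c] for p, c in r.products],
                "bidirectional": r.bidirectional,
            }
            for r in model.reactions
        ],
        "equalities": [{"coeffs": dict(eq.coeffs), "rhs": eq.rhs} for eq in model.equalities],
        "net_bounds": {n: _bound_out(b) for n, b in model.net_bounds.items()},
        "xch_bounds": {n: _bound_out(b) for n, b in model.xch_bounds.items()},
        "groups": [
            {
                "id": g.id,
                "pool": g.pool,
                "atoms": [a + 1 for a in g.atoms],
                "times": "inf" if g.timepoints is None else list(g.timepoints),
                "sd": list(g.sd),
            }
            for g in model.measurements.groups
        ],
        "experiments": [
            {
                "id": e.id,
                "inputs": [
                    {"pool": m.pool, "components": [[p, f] for p, f in m.components]}
                    for m in e.inputs
                ],
                "groups": list(e.group_ids),
            }
            for e in model.measurements.experiments
        ],
    }


def model_from_dict(doc: dict, name: str = "model") -> NetworkModel:
    for key in ("pools", "reactions"):
        if key not in doc:
            raise SemanticError(f"missing {key!r} key", element="model")
    pools = tuple(
        Pool(
            name=p["name"],
            n_atoms=int(p["atoms"]),
            is_substrate=bool(p.get("substrate", False)),
            is_excreted=bool(p.get("excreted", False)),
        )
        for p in doc["pools"]
    )
    reactions = tuple(
        Reaction(
            name=r["name"],
            educts=tuple((p, c) for p, c in r["educts"]),
            products=tuple((p, c) for p, c in r.get("products", [])),
            bidirectional=bool(r.get("bidirectional", False)),
        )
        for r in doc["reactions"]
    )
    equalities = tuple(
        LinearConstraint(coeffs={k: float(v) for k, v in eq["coeffs"].items()}, rhs=float(eq["rhs"]))
        for eq in doc.get("equalities", [])
    )
    groups = tuple(
        MsGroup(
            id=g["id"],
            pool=g["pool"],
            atoms=tuple(int(a) - 1 for a in g["atoms"]),
            timepoints=None if g.get("times", "inf") == "inf" else tuple(float(t) for t in g["times"]),
            sd=tuple(float(s) for s in g["sd"]),
        )
        for g in doc.get("groups", [])
    )
    experiments = tuple(
        Experiment(
            id=e["id"],
            inputs=tuple(
                InputMixture(pool=m["pool"], components=tuple((p, float(f)) for p, f in m["components"]))
                for m in e.get("inputs", [])
            ),
            group_ids=tuple(e.get("groups", [])),
        )
        for e in doc.get("experiments", [])
    )
    model = NetworkModel(
        name=doc.get("name", name),
        pools=pools,
        reactions=reactions,
        equalities=equalities,
        net_bounds={n: _bound_in(b) for n, b in doc.get("net_bounds", {}).items()},
        xch_bounds={n: _bound_in(b) for n, b in doc.get("xch_bounds", {}).items()},
        measurements=MeasurementConfig(groups=groups, experiments=experiments),
    )
    return assert_valid(model)


def parse_json_model(path: str | Path) -> NetworkModel:
    """Parse the JSON dialect; semantics identical to :func:`parse_fluxml`."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelError(f"malformed JSON in {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise SemanticError("top-level JSON value must be an object", element="model")
    return model_from_dict(doc, name=path.stem)


def write_json(model: NetworkModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1) + "\n")
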