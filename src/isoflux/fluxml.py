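"""Reader/writer for a documented subset of the FluxML model language.

Supported elements::

    <fluxml name="...">
      <metabolitepools>
        <pool id="A" atoms="2" [excreted="true"]/> ...
      </metabolitepools>
      <reactionnetwork>
        <reaction id="v1" [bidirectional="true"]>
          <reduct id="A" cfg="ab"/> ... <rproduct id="B" cfg="ab"/> ...
        </reaction> ...
      </reactionnetwork>
      <constraints>
        <net>v1 = 1; v2 &gt;= 0.05; v2 &lt;= 0.95</net>
        <xch>v2 &lt;= 2</xch>
      </constraints>
      <configuration id="exp1">
        <input pool="A">
          <label cfg="11" purity="0.5"/> ...
        </input>
        <measurement>
          <group id="gC" spec="C#M(1,2)" times="0.5 1 2" sd="0.01"/> ...
        </measurement>
      </configuration> ...

Everything else is rejected with an explicit "unsupported feature" error
rather than silently ignored.  Substrate pools are those that appear as an
``<input>`` of some configuration.  Atom indices in ``spec`` ranges are
1-based; ``times="inf"`` marks an isotopically stationary measurement.
General (multi-variable) inequalities are outside the subset; inequality
statements must be simple bounds on one flux.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
from lxml import etree

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

__all__ = ["parse_fluxml", "write_fluxml", "parse_constraint_text"]

_TOKEN = re.compile(r"\s*(?:(?P<num>\d+\.?\d*(?:[eE][+-]?\d+)?)|(?P<name>[A-Za-z_]\w*)"
                    r"|(?P<op>[+\-*]|<=|>=|=))")


def _tokenize(stmt: str) -> list[tuple[str, str]]:
    tokens = []
    pos = 0
    while pos < len(stmt):
        m = _TOKEN.match(stmt, pos)
        if m is None:
            if stmt[pos:].strip() == "":
                break
            raise SemanticError(f"cannot parse constraint near {stmt[pos:]!r}", element="constraints")
        pos = m.end()
        for kind in ("num", "name", "op"):
            if m.group(kind) is not None:
                tokens.append((kind, m.group(kind)))
    return tokens


def _parse_linear(tokens: list[tuple[str, str]]) -> tuple[dict[str, float], float]:
    """Parse a linear expression into (coeffs by flux name, constant)."""
    coeffs: dict[str, float] = {}
    const = 0.0
    sign = 1.0
    pending: float | None = None
    i = 0
    while i < len(tokens):
        kind, val = tokens[i]
        if kind == "op" and val in "+-":
            if pending is not None:
                const += sign * pending
                pending = None
            sign = 1.0 if val == "+" else -1.0
        elif kind == "num":
            pending = float(val)
            # optional '*' then name
            if i + 1 < len(tokens) and tokens[i + 1] == ("op", "*"):
                i += 1
        elif kind == "name":
            coef = sign * (1.0 if pending is None else pending)
            coeffs[val] = coeffs.get(val, 0.0) + coef
            pending = None
            sign = 1.0
        else:
            raise SemanticError(f"unexpected token {val!r} in constraint", element="constraints")
        i += 1
    if pending is not None:
        const += sign * pending
    return coeffs, const


def parse_constraint_text(
    text: str,
) -> tuple[list[LinearConstraint], dict[str, tuple[float, float]]]:
    """Parse ``;``-separated linear statements into equalities and bounds.

    Statements with ``=`` become :class:`LinearConstraint` rows; ``<=`` and
    ``>=`` must involve a single flux with unit coefficient and become
    bound updates.
    """
    equalities: list[LinearConstraint] = []
    bounds: dict[str, tuple[float, float]] = {}
    for stmt in text.split(";"):
        if not stmt.strip():
            continue
        tokens = _tokenize(stmt)
        rel_idx = [i for i, (k, v) in enumerate(tokens) if k == "op" and v in ("=", "<=", ">=")]
        if len(rel_idx) != 1:
            raise SemanticError(
                f"constraint {stmt.strip()!r} must contain exactly one relation",
                element="constraints",
            )
        i = rel_idx[0]
        rel = tokens[i][1]
        lc, lconst = _parse_linear(tokens[:i])
        rc, rconst = _parse_linear(tokens[i + 1:])
        # move variables left, constants right
        coeffs = dict(lc)
        for name, c in rc.items():
            coeffs[name] = coeffs.get(name, 0.0) - c
        rhs = rconst - lconst
        coeffs = {n: c for n, c in coeffs.items() if c != 0.0}
        if rel == "=":
            equalities.append(LinearConstraint(coeffs=coeffs, rhs=rhs))
            continue
        if len(coeffs) != 1:
            raise SemanticError(
                f"unsupported feature: general inequality {stmt.strip()!r} "
                "(only single-flux bounds are in the subset)",
                element="constraints",
            )
        (name, c), = coeffs.items()
        val = rhs / c
        upper = (rel == "<=") == (c > 0)
        lo, hi = bounds.get(name, (-np.inf, np.inf))
        bounds[name] = (lo, min(hi, val)) if upper else (max(lo, val), hi)
    return equalities, bounds


_SPEC = re.compile(r"^(?P<pool>\w+)#M\((?P<lo>\d+)(?:,(?P<hi>\d+))?\)$")


def _parse_group(el: etree._Element) -> MsGroup:
    gid = el.get("id")
    spec = el.get("spec")
    if gid is None or spec is None:
        raise SemanticError("group needs 'id' and 'spec'", element="group", line=el.sourceline)
    m = _SPEC.match(spec)
    if m is None:
        raise SemanticError(
            f"unsupported feature: measurement spec {spec!r} (expected POOL#M(lo,hi))",
            element=f"group {gid}",
            line=el.sourceline,
        )
    lo = int(m.group("lo"))
    hi = int(m.group("hi")) if m.group("hi") else lo
    if lo < 1 or hi < lo:
        raise SemanticError(f"bad atom range in {spec!r}", element=f"group {gid}", line=el.sourceline)
    atoms = tuple(range(lo - 1, hi))  # to 0-based
    times_attr = (el.get("times") or "inf").strip()
    if times_attr == "inf":
        times: tuple[float, ...] | None = None
    else:
        times = tuple(float(t) for t in re.split(r"[,\s]+", times_attr) if t)
    sd_attr = (el.get("sd") or "").strip()
    if not sd_attr:
        raise SemanticError("group needs 'sd'", element=f"group {gid}", line=el.sourceline)
    sd_vals = [float(s) for s in re.split(r"[,\s]+", sd_attr) if s]
    n_shifts = len(atoms) + 1
    if len(sd_vals) == 1:
        sd_vals = sd_vals * n_shifts
    return MsGroup(id=gid, pool=m.group("pool"), atoms=atoms, timepoints=times, sd=tuple(sd_vals))


def parse_fluxml(path: str | Path) -> NetworkModel:
    """Parse a FluxML-subset file into a validated :class:`NetworkModel`."""
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ModelError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "fluxml":
        raise SemanticError(f"unsupported feature: root element <{root.tag}>", element=root.tag)

    pools_raw: dict[str, tuple[int, bool]] = {}
    reactions: list[Reaction] = []
    equalities: list[LinearConstraint] = []
    net_bounds: dict[str, tuple[float, float]] = {}
    xch_bounds: dict[str, tuple[float, float]] = {}
    groups: list[MsGroup] = []
    experiments: list[Experiment] = []

    for section in root:
        if section.tag is etree.Comment:
            continue
        if section.tag == "metabolitepools":
            for el in section:
                if el.tag != "pool":
                    raise SemanticError(
                        f"unsupported feature: element <{el.tag}>", element=el.tag, line=el.sourceline
                    )
                pools_raw[el.get("id")] = (
                    int(el.get("atoms", "0")),
                    el.get("excreted", "false").lower() == "true",
                )
        elif section.tag == "reactionnetwork":
            for el in section:
                if el.tag != "reaction":
                    raise SemanticError(
                        f"unsupported feature: element <{el.tag}>", element=el.tag, line=el.sourceline
                    )
                educts, products = [], []
                for part in el:
                    cfg = part.get("cfg", "")
                    if part.tag == "reduct":
                        educts.append((part.get("id"), cfg))
                    elif part.tag == "rproduct":
                        products.append((part.get("id"), cfg))
                    else:
                        raise SemanticError(
                            f"unsupported feature: element <{part.tag}>",
                            element=part.tag,
                            line=part.sourceline,
                        )
                reactions.append(
                    Reaction(
                        name=el.get("id"),
                        educts=tuple(educts),
                        products=tuple(products),
                        bidirectional=el.get("bidirectional", "false").lower() == "true",
                    )
                )
        elif section.tag == "constraints":
            for el in section:
                if el.tag == "net":
                    eqs, bnds = parse_constraint_text(el.text or "")
                    equalities.extend(eqs)
                    net_bounds.update(bnds)
                elif el.tag == "xch":
                    eqs, bnds = parse_constraint_text(el.text or "")
                    if eqs:
                        raise SemanticError(
                            "unsupported feature: equality constraints on exchange fluxes",
                            element="xch",
                            line=el.sourceline,
                        )
                    xch_bounds.update(bnds)
                else:
                    raise SemanticError(
                        f"unsupported feature: element <{el.tag}>", element=el.tag, line=el.sourceline
                    )
        elif section.tag == "configuration":
            eid = section.get("id") or f"exp{len(experiments) + 1}"
            inputs: list[InputMixture] = []
            gids: list[str] = []
            for el in section:
                if el.tag == "input":
                    comps = []
                    for lab in el:
                        if lab.tag != "label":
                            raise SemanticError(
                                f"unsupported feature: element <{lab.tag}>",
                                element=lab.tag,
                                line=lab.sourceline,
                            )
                        comps.append((lab.get("cfg"), float(lab.get("purity"))))
                    inputs.append(InputMixture(pool=el.get("pool"), components=tuple(comps)))
                elif el.tag == "measurement":
                    for gel in el:
                        if gel.tag != "group":
                            raise SemanticError(
                                f"unsupported feature: element <{gel.tag}>",
                                element=gel.tag,
                                line=gel.sourceline,
                            )
                        g = _parse_group(gel)
                        if all(h.id != g.id for h in groups):
                            groups.append(g)
                        gids.append(g.id)
                else:
                    raise SemanticError(
                        f"unsupported feature: element <{el.tag}>", element=el.tag, line=el.sourceline
                    )
            experiments.append(Experiment(id=eid, inputs=tuple(inputs), group_ids=tuple(gids)))
        else:
            raise SemanticError(
                f"unsupported feature: element <{section.tag}>",
                element=section.tag,
                line=section.sourceline,
            )

    substrate_pools = {mix.pool for e in experiments for mix in e.inputs}
    pools = tuple(
        Pool(name=n, n_atoms=a, is_substrate=n in substrate_pools, is_excreted=exc)
        for n, (a, exc) in pools_raw.items()
    )
    model = NetworkModel(
        name=root.get("name") or path.stem,
        pools=pools,
        reactions=tuple(reactions),
        equalities=tuple(equalities),
        net_bounds=net_bounds,
        xch_bounds=xch_bounds,
        measurements=MeasurementConfig(groups=tuple(groups), experiments=tuple(experiments)),
    )
    return assert_valid(model)


def _fmt(x: float) -> str:
    return format(x, ".12g")


def write_fluxml(model: NetworkModel, path: str | Path) -> None:
    """Serialize a model back to the FluxML subset (inverse of :func:`parse_fluxml`)."""
    root = etree.Element("fluxml", name=model.name)
    mp = etree.SubElement(root, "metabolitepools")
    for p in model.pools:
        el = etree.SubElement(mp, "pool", id=p.name, atoms=str(p.n_atoms))
        if p.is_excreted:
            el.set("excreted", "true")
    rn = etree.SubElement(root, "reactionnetwork")
    for r in model.reactions:
        el = etree.SubElement(rn, "reaction", id=r.name)
        if r.bidirectional:
            el.set("bidirectional", "true")
        for pname, cfg in r.educts:
            etree.SubElement(el, "reduct", id=pname, cfg=cfg)
        for pname, cfg in r.products:
            etree.SubElement(el, "rproduct", id=pname, cfg=cfg)

    stmts_net = []
    for eq in model.equalities:
        lhs = " + ".join(f"{_fmt(c)}*{n}" for n, c in eq.coeffs.items())
        stmts_net.append(f"{lhs} = {_fmt(eq.rhs)}")
    for n, (lo, hi) in model.net_bounds.items():
        if np.isfinite(lo):
            stmts_net.append(f"{n} >= {_fmt(lo)}")
        if np.isfinite(hi):
            stmts_net.append(f"{n} <= {_fmt(hi)}")
    stmts_xch = []
    for n, (lo, hi) in model.xch_bounds.items():
        if np.isfinite(lo) and lo != 0.0:
            stmts_xch.append(f"{n} >= {_fmt(lo)}")
        if lo == 0.0 and hi == 0.0:
            stmts_xch.append(f"{n} <= 0")
        elif np.isfinite(hi):
            stmts_xch.append(f"{n} <= {_fmt(hi)}")
    if stmts_net or stmts_xch:
        cons = etree.SubElement(root, "constraints")
        if stmts_net:
            etree.SubElement(cons, "net").text = "; ".join(stmts_net)
        if stmts_xch:
            etree.SubElement(cons, "xch").text = "; ".join(stmts_xch)

    for e in model.measurements.experiments:
        cfg = etree.SubElement(root, "configuration", id=e.id)
        for mix in e.inputs:
            iel = etree.SubElement(cfg, "input", pool=mix.pool)
            for pattern, frac in mix.components:
                etree.SubElement(iel, "label", cfg=pattern, purity=_fmt(frac))
        if e.group_ids:
            mel = etree.SubElement(cfg, "measurement")
            for gid in e.group_ids:
                g = model.measurements.group(gid)
                if g.atoms != tuple(range(g.atoms[0], g.atoms[-1] + 1)):
                    raise SemanticError(
                        f"group {g.id!r}: non-contiguous atom sets cannot be "
                        "expressed in the FluxML subset (use the JSON dialect)"
                    )
                lo, hi = g.atoms[0] + 1, g.atoms[-1] + 1
                spec = f"{g.pool}#M({lo},{hi})" if hi > lo else f"{g.pool}#M({lo})"
                attrs = {
                    "id": g.id,
                    "spec": spec,
                    "times": "inf"
                    if g.timepoints is None
                    else " ".join(_fmt(t) for t in g.timepoints),
                    "sd": " ".join(_fmt(s) for s in g.sd),
                }
                etree.SubElement(mel, "group", **attrs)

    Path(path).write_bytes(
        etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")
    )
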