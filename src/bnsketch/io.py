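"""File formats: .bnet networks, sketch JSON, .aeon-style models, observation tables.

The sketch file is a JSON document with sections

``variables``
    ordered list of variable names;
``influences``
    list of edges, either ``[source, target]`` pairs or objects
    ``{"source": .., "target": .., "sign": "+"|"-"|"?", "essential": bool}``;
    a sign generates a monotonicity property on the target (conjoined with
    essentiality when the edge is marked essential);
``symbols``
    mapping symbol name -> arity;
``update_expressions``
    mapping variable -> expression string; a variable without an entry gets
    a fresh uninterpreted symbol applied to all its regulators;
``properties``
    list of ``{"target": variable, "property": "essential(v1) & ..."}``;
``hctl``
    list of closed HCTL formula strings.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd

from . import hctl as H
from . import psbn as P
from . import sketch as SK
from .datagen import ObservationTable

__all__ = ["read_bnet", "write_bnet", "read_sketch", "write_sketch",
           "read_aeon", "read_observations", "sketch_to_dict",
           "sketch_from_dict", "SketchFormatError"]


class SketchFormatError(ValueError):
    """A sketch or network file violates its schema; names the section."""


# ---------------------------------------------------------------------------
# .bnet (BoolNet "targets, factors")
# ---------------------------------------------------------------------------

def read_bnet(path: Union[str, Path]) -> P.BooleanNetwork:
    """Read a fully specified network in BoolNet's ``targets, factors`` format."""
    lines = Path(path).read_text().splitlines()
    rows: List[Tuple[str, str]] = []
    header_seen = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            if [p.strip().lower() for p in line.split(",", 1)] != ["targets", "factors"]:
                raise SketchFormatError(
                    f"line {lineno}: expected header 'targets, factors'")
            header_seen = True
            continue
        if "," not in line:
            raise SketchFormatError(f"line {lineno}: expected 'target, factor'")
        target, factor = line.split(",", 1)
        rows.append((target.strip(), factor.strip()))
    if not header_seen:
        raise SketchFormatError("missing 'targets, factors' header")
    if not rows:
        raise SketchFormatError("no update rows")
    variables = tuple(t for t, _ in rows)
    if len(set(variables)) != len(variables):
        dupes = sorted({t for t in variables if variables.count(t) > 1})
        raise SketchFormatError(f"duplicate target rows for {dupes}")
    exprs = []
    for target, factor in rows:
        try:
            exprs.append(P.parse_expression(factor, variables))
        except ValueError as exc:
            raise SketchFormatError(f"update of {target!r}: {exc}") from exc
    return P.specialize(P.PSBN(variables, tuple(exprs)), {})


def _table_expression_text(table: Sequence[int], variables: Sequence[str]) -> str:
    n = len(variables)
    ones = [r for r in range(1 << n) if table[r]]
    if not ones:
        return "0"
    if len(ones) == 1 << n:
        return "1"
    terms = []
    for row in ones:
        bits = P.index_state(row, n)
        lits = [v if b else f"!{v}" for v, b in zip(variables, bits)]
        terms.append(" & ".join(lits) if len(lits) > 1 else lits[0])
    return " | ".join(f"({t})" if len(ones) > 1 and " & " in t else t
                      for t in terms)


def write_bnet(network: P.BooleanNetwork, path: Union[str, Path]) -> None:
    """Write a network in ``targets, factors`` form (minterm expressions)."""
    lines = ["targets, factors"]
    for v, table in zip(network.variables, network.tables):
        lines.append(f"{v}, {_table_expression_text(table, network.variables)}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Sketch JSON
# ---------------------------------------------------------------------------

def sketch_from_dict(doc: dict) -> SK.Sketch:
    if not isinstance(doc, dict):
        raise SketchFormatError("sketch document must be a JSON object")
    try:
        variables = tuple(doc["variables"])
    except KeyError:
        raise SketchFormatError("section 'variables' is required") from None
    if len(set(variables)) != len(variables):
        raise SketchFormatError("section 'variables': duplicate names")

    edges = set()
    signs: Dict[Tuple[str, str], str] = {}
    essential = set()
    for entry in doc.get("influences", []):
        if isinstance(entry, dict):
            try:
                edge = (entry["source"], entry["target"])
            except KeyError as exc:
                raise SketchFormatError(
                    f"section 'influences': missing {exc.args[0]!r}") from None
            if "sign" in entry:
                signs[edge] = entry["sign"]
            if entry.get("essential"):
                essential.add(edge)
        else:
            if len(entry) != 2:
                raise SketchFormatError(
                    f"section 'influences': bad edge {entry!r}")
            edge = (entry[0], entry[1])
        edges.add(edge)
    try:
        ig = SK.InfluenceGraph(variables, frozenset(edges), signs,
                               frozenset(essential))
    except ValueError as exc:
        raise SketchFormatError(f"section 'influences': {exc}") from exc

    symbols: Dict[str, P.FunctionSymbol] = {}
    for name, arity in dict(doc.get("symbols", {})).items():
        symbols[name] = P.FunctionSymbol(name, int(arity))

    updates = dict(doc.get("update_expressions", {}))
    unknown = set(updates) - set(variables)
    if unknown:
        raise SketchFormatError(
            f"section 'update_expressions': unknown variables {sorted(unknown)}")
    expressions = []
    for v in variables:
        if v in updates:
            try:
                expressions.append(P.parse_expression(updates[v], variables, symbols))
            except ValueError as exc:
                raise SketchFormatError(
                    f"section 'update_expressions', variable {v!r}: {exc}") from exc
        else:
            # default: a fresh unconstrained function of all regulators
            preds = ig.predecessors(v)
            name = f"f_{v}"
            while name in symbols or name in variables:
                name += "_"
            sym = P.FunctionSymbol(name, len(preds))
            symbols[name] = sym
            var_index = {w: i for i, w in enumerate(variables)}
            expressions.append(P.App(sym, tuple(
                P.Var(p, var_index[p]) for p in preds)))
    try:
        psbn = P.PSBN(variables, tuple(expressions))
    except ValueError as exc:
        raise SketchFormatError(f"section 'update_expressions': {exc}") from exc

    index = {v: i for i, v in enumerate(variables)}
    ufp: List[SK.UFPItem] = []
    # properties generated from signed / essential influences
    for (src, tgt), sign in signs.items():
        atom: Optional[SK.FunctionProperty] = None
        if sign == "+":
            atom = SK.Positive(src)
        elif sign == "-":
            atom = SK.Negative(src)
        if atom is not None and (src, tgt) in essential:
            atom = SK.PAnd(atom, SK.Essential(src))
        if atom is not None:
            ufp.append(SK.UFPItem(index[tgt], atom))
    for src, tgt in sorted(essential):
        if signs.get((src, tgt)) in (None, "?"):
            ufp.append(SK.UFPItem(index[tgt], SK.Essential(src)))
    # explicitly listed properties
    for entry in doc.get("properties", []):
        try:
            target, text = entry["target"], entry["property"]
        except (TypeError, KeyError):
            raise SketchFormatError(
                f"section 'properties': bad entry {entry!r}") from None
        if target not in index:
            raise SketchFormatError(
                f"section 'properties': unknown variable {target!r}")
        try:
            prop = SK.parse_property(text, variables)
        except ValueError as exc:
            raise SketchFormatError(f"section 'properties': {exc}") from exc
        ufp.append(SK.UFPItem(index[target], prop))

    dynamic = []
    for text in doc.get("hctl", []):
        try:
            phi = H.parse_hctl(text, variables)
        except ValueError as exc:
            raise SketchFormatError(f"section 'hctl': {exc}") from exc
        if not H.check_closed(phi):
            raise SketchFormatError(
                f"section 'hctl': formula {text!r} has free state variables "
                f"{sorted(H.free_svars(phi))}; dynamic properties must be closed")
        dynamic.append(phi)

    return SK.Sketch(ig, psbn, tuple(ufp), tuple(dynamic))


def sketch_to_dict(sketch: SK.Sketch) -> dict:
    variables = list(sketch.variables)
    influences = []
    for src, tgt in sorted(sketch.ig.edges):
        entry: dict = {"source": src, "target": tgt}
        if (src, tgt) in sketch.ig.signs:
            entry["sign"] = sketch.ig.signs[(src, tgt)]
        if (src, tgt) in sketch.ig.essential:
            entry["essential"] = True
        influences.append(entry)
    symbols = {name: sym.arity for name, sym in sketch.psbn.symbols().items()}
    updates = {v: P.format_expression(e)
               for v, e in zip(variables, sketch.psbn.expressions)}
    properties = [{"target": variables[item.target],
                   "property": SK.format_property(item.property)}
                  for item in sketch.ufp]
    hctl = [H.format_hctl(f) for f in sketch.dynamic]
    return {"variables": variables, "influences": influences,
            "symbols": symbols, "update_expressions": updates,
            "properties": properties, "hctl": hctl}


def read_sketch(path: Union[str, Path]) -> SK.Sketch:
    text = Path(path).read_text()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SketchFormatError(f"not valid JSON: {exc}") from exc
    return sketch_from_dict(doc)


def write_sketch(sketch: SK.Sketch, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(sketch_to_dict(sketch), indent=2) + "\n")


# ---------------------------------------------------------------------------
# Minimal .aeon-style dialect (read-only)
# ---------------------------------------------------------------------------

def read_aeon(path: Union[str, Path]) -> SK.Sketch:
    """Read a minimal .aeon-style model as a sketch.

    Supported lines: comments (``#``), regulations ``a -> b`` / ``a -| b``
    with an optional ``?`` suffix marking the regulation as non-essential,
    and update functions ``$v: expression``.  Variables without an update
    function get a fresh symbol over their regulators; signed regulations
    generate monotonicity properties (conjoined with essentiality unless
    suffixed ``?``).
    """
    lines = Path(path).read_text().splitlines()
    order: List[str] = []
    edges: List[Tuple[str, str, str, bool]] = []
    updates: Dict[str, str] = {}

    def note(v: str) -> None:
        if v not in order:
            order.append(v)

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("$"):
            head, sep, expr = line[1:].partition(":")
            if not sep:
                raise SketchFormatError(f"line {lineno}: expected '$var: expression'")
            note(head.strip())
            updates[head.strip()] = expr.strip()
            continue
        arrow = None
        for marker in ("->?", "-|?", "->", "-|"):
            if marker in line:
                arrow = marker
                break
        if arrow is None:
            raise SketchFormatError(f"line {lineno}: unrecognized line {line!r}")
        src, _, tgt = line.partition(arrow)
        src, tgt = src.strip(), tgt.strip()
        if not src or not tgt:
            raise SketchFormatError(f"line {lineno}: bad regulation {line!r}")
        sign = "+" if arrow.startswith("->") else "-"
        observable = not arrow.endswith("?")
        note(src)
        note(tgt)
        edges.append((src, tgt, sign, observable))

    variables = list(order)
    doc: dict = {
        "variables": variables,
        "influences": [{"source": s, "target": t, "sign": g, "essential": o}
                       for s, t, g, o in edges],
        "update_expressions": {},
        "symbols": {},
        "hctl": [],
    }
    # infer symbol declarations from applications in update expressions
    symbols: Dict[str, int] = {}
    for v, text in updates.items():
        for name, arity in _scan_symbols(text, set(variables)).items():
            prev = symbols.setdefault(name, arity)
            if prev != arity:
                raise SketchFormatError(
                    f"symbol {name!r} used with arities {prev} and {arity}")
        doc["update_expressions"][v] = text
    doc["symbols"] = symbols
    return sketch_from_dict(doc)


def _scan_symbols(text: str, variables: set) -> Dict[str, int]:
    """Guess symbol arities from ``name(...)`` applications and bare names."""
    out: Dict[str, int] = {}
    toks = P._tokenize(text)
    for i, (kind, val, _) in enumerate(toks):
        if kind != "ident" or val in variables:
            continue
        if toks[i + 1][1] == "(":
            depth = 0
            arity = 0
            saw_any = False
            for kind2, val2, _ in toks[i + 1:]:
                if val2 == "(":
                    depth += 1
                elif val2 == ")":
                    depth -= 1
                    if depth == 0:
                        break
                elif depth == 1:
                    saw_any = True
                    if val2 == ",":
                        arity += 1
            out[val] = arity + 1 if saw_any else 0
        else:
            out[val] = 0
    return out


# ---------------------------------------------------------------------------
# Observation tables (CSV/TSV)
# ---------------------------------------------------------------------------

def read_observations(path: Union[str, Path], kind: str = "steady_state"
                      ) -> ObservationTable:
    """Read a binarized observation table.

    Header row: experiment-id column followed by variable names; cells are
    0, 1 or NA (empty also counts as unmeasured).  Tab- or comma-separated,
    decided by the file suffix (.tsv uses tabs).
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if frame.shape[1] < 2:
        raise SketchFormatError("observation table needs an id column and data")
    variables = tuple(frame.columns[1:])
    rows = []
    for _, record in frame.iterrows():
        values = []
        for v in variables:
            cell = str(record[v]).strip()
            if cell in ("", "NA", "na", "NaN", "nan", "?"):
                values.append(None)
            elif cell in ("0", "1"):
                values.append(int(cell))
            else:
                raise SketchFormatError(
                    f"observation {record.iloc[0]!r}, variable {v!r}: "
                    f"cell {cell!r} is not 0/1/NA")
        rows.append((str(record.iloc[0]), tuple(values)))
    return ObservationTable(variables, tuple(rows), kind)  # type: ignore[arg-type]
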