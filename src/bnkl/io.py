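"""Network readers and writers: BIF and a JSON dialect.

The BIF dialect is the JavaBayes/bnlearn "network / variable / probability"
grammar, as distributed by the bnlearn network repository.  Parsing is
whitespace-insensitive and case-sensitive; ``//``, ``/* */`` and ``#``
comments and ``property`` statements are accepted and ignored.  Probability
blocks may use per-parent-configuration rows ``( s1, s2 ) v, v;`` or the
``table`` form; in the latter the child variable varies slowest and parent
configurations are enumerated row-major in the declared parent order.

The writer emits floats with ``repr`` (shortest round-tripping form), so
``read_bif(write_bif(N))`` reproduces the network exactly, bit for bit.

Rounded parameters are common in published networks, so normalization is
validated leniently by default: a CPT column whose sum deviates from 1 by
more than 1e-6 produces a warning; with ``strict=True`` it is an error.
Structural problems (cycles, bad scopes, negative values) always raise.
"""

from __future__ import annotations

import bisect
import json
import re
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np

from .network import BayesianNetwork, NetworkError
from .potentials import Potential, Variable, canonical_scope

__all__ = [
    "ParseError",
    "FormatError",
    "read_bif",
    "loads_bif",
    "write_bif",
    "dumps_bif",
    "read_json",
    "write_json",
    "network_to_dict",
    "network_from_dict",
    "read_network",
]


class ParseError(ValueError):
    """Syntax error in an input file; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


class FormatError(ValueError):
    """Well-formed syntax but invalid content (duplicates, bad tables...)."""


_TOKEN = re.compile(
    r"//[^\n]*|/\*.*?\*/|#[^\n]*|[{}()\[\]|,;]|[^\s{}()\[\]|,;]+", re.S
)
_PUNCT = set("{}()[]|,;")


class _Tokens:
    def __init__(self, text: str):
        newlines = [i for i, c in enumerate(text) if c == "\n"]
        self.items: list[tuple[str, int]] = []
        for m in _TOKEN.finditer(text):
            tok = m.group()
            if tok[0] in "#/" and tok not in _PUNCT and (
                tok.startswith("//") or tok.startswith("/*") or tok.startswith("#")
            ):
                continue
            line = bisect.bisect_right(newlines, m.start()) + 1
            self.items.append((tok, line))
        self.pos = 0

    @property
    def at_end(self) -> bool:
        return self.pos >= len(self.items)

    @property
    def line(self) -> int:
        if self.at_end:
            return self.items[-1][1] if self.items else 1
        return self.items[self.pos][1]

    def peek(self) -> str | None:
        return None if self.at_end else self.items[self.pos][0]

    def next(self) -> str:
        if self.at_end:
            raise ParseError("unexpected end of input", self.line)
        tok, _ = self.items[self.pos]
        self.pos += 1
        return tok

    def expect(self, tok: str) -> None:
        got = self.next()
        if got != tok:
            raise ParseError(f"expected {tok!r}, found {got!r}", self.items[self.pos - 1][1])

    def skip_block(self) -> None:
        """Skip a balanced { ... } block (the '{' not yet consumed)."""
        self.expect("{")
        depth = 1
        while depth:
            t = self.next()
            if t == "{":
                depth += 1
            elif t == "}":
                depth -= 1

    def skip_statement(self) -> None:
        while self.next() != ";":
            pass


def _number(tok: str, line: int) -> float:
    try:
        return float(tok)
    except ValueError:
        raise ParseError(f"expected a number, found {tok!r}", line) from None


def _read_values(tk: _Tokens) -> list[float]:
    vals: list[float] = []
    while True:
        t = tk.next()
        if t == ";":
            return vals
        if t == ",":
            continue
        vals.append(_number(t, tk.items[tk.pos - 1][1]))


def loads_bif(text: str, *, strict: bool = False, name_hint: str = "network") -> BayesianNetwork:
    """Parse a BIF document from a string."""
    tk = _Tokens(text)
    net_name: str | None = None
    states: dict[str, tuple[str, ...]] = {}
    decl_line: dict[str, int] = {}
    parent_decl: dict[str, tuple[str, ...]] = {}
    prob_rows: dict[str, tuple[int, object]] = {}  # child -> (line, payload)

    while not tk.at_end:
        tok = tk.next()
        line = tk.items[tk.pos - 1][1]
        if tok == "network":
            parts = []
            while tk.peek() != "{":
                parts.append(tk.next())
            net_name = " ".join(parts) or None
            tk.skip_block()
        elif tok == "variable":
            vname = tk.next()
            if vname in states:
                raise FormatError(
                    f"duplicate variable declaration {vname!r} "
                    f"(lines {decl_line[vname]} and {line})"
                )
            tk.expect("{")
            labels: list[str] | None = None
            declared_n: int | None = None
            while True:
                t = tk.next()
                if t == "}":
                    break
                if t == "property":
                    tk.skip_statement()
                elif t == "type":
                    kind = tk.next()
                    if kind != "discrete":
                        raise ParseError(
                            f"unsupported variable type {kind!r}", tk.items[tk.pos - 1][1]
                        )
                    tk.expect("[")
                    declared_n = int(_number(tk.next(), tk.line))
                    tk.expect("]")
                    tk.expect("{")
                    labels = []
                    while True:
                        s = tk.next()
                        if s == "}":
                            break
                        if s != ",":
                            labels.append(s)
                    if tk.peek() == ";":
                        tk.next()
                else:
                    raise ParseError(f"unexpected token {t!r} in variable block", tk.line)
            if labels is None:
                raise ParseError(f"variable {vname!r} has no type declaration", line)
            if declared_n is not None and declared_n != len(labels):
                raise ParseError(
                    f"variable {vname!r} declares {declared_n} states but lists "
                    f"{len(labels)}",
                    line,
                )
            states[vname] = tuple(labels)
            decl_line[vname] = line
        elif tok == "probability":
            tk.expect("(")
            child = tk.next()
            parents: list[str] = []
            t = tk.next()
            if t == "|":
                while True:
                    t = tk.next()
                    if t == ")":
                        break
                    if t != ",":
                        parents.append(t)
            elif t != ")":
                raise ParseError(f"expected '|' or ')', found {t!r}", tk.line)
            if child in prob_rows:
                raise FormatError(f"duplicate probability block for {child!r} (line {line})")
            tk.expect("{")
            table_vals: list[float] | None = None
            rows: list[tuple[int, tuple[str, ...], list[float]]] = []
            while True:
                t = tk.next()
                if t == "}":
                    break
                row_line = tk.items[tk.pos - 1][1]
                if t == "property":
                    tk.skip_statement()
                elif t == "table":
                    table_vals = _read_values(tk)
                elif t == "(":
                    labels = []
                    while True:
                        s = tk.next()
                        if s == ")":
                            break
                        if s != ",":
                            labels.append(s)
                    rows.append((row_line, tuple(labels), _read_values(tk)))
                else:
                    raise ParseError(
                        f"unexpected token {t!r} in probability block", row_line
                    )
            parent_decl[child] = tuple(parents)
            prob_rows[child] = (line, table_vals if table_vals is not None else rows)
        else:
            raise ParseError(f"unexpected top-level token {tok!r}", line)

    # -- assemble CPT arrays ------------------------------------------------
    tables: dict[str, np.ndarray] = {}
    for vname in states:
        if vname not in prob_rows:
            raise FormatError(f"no probability block for variable {vname!r}")
    for child, (line, payload) in prob_rows.items():
        if child not in states:
            raise ParseError(f"probability block for undeclared variable {child!r}", line)
        parents = parent_decl[child]
        for p in parents:
            if p not in states:
                raise ParseError(
                    f"probability block for {child!r} names undeclared parent {p!r}", line
                )
        shape = (len(states[child]),) + tuple(len(states[p]) for p in parents)
        if isinstance(payload, list) and payload and isinstance(payload[0], float):
            flat = np.asarray(payload, dtype=float)
            if flat.size != int(np.prod(shape)):
                raise ParseError(
                    f"table for {child!r} has {flat.size} values, expected "
                    f"{int(np.prod(shape))}",
                    line,
                )
            tables[child] = flat.reshape(shape)
        else:
            arr = np.full(shape, np.nan)
            seen_rows: set[tuple[str, ...]] = set()
            for row_line, labels, vals in payload:  # type: ignore[union-attr]
                if len(labels) != len(parents):
                    raise ParseError(
                        f"row for {child!r} gives {len(labels)} parent states, "
                        f"expected {len(parents)}",
                        row_line,
                    )
                if labels in seen_rows:
                    raise FormatError(
                        f"duplicate row {labels} for {child!r} (line {row_line})"
                    )
                seen_rows.add(labels)
                pidx = []
                for p, lab in zip(parents, labels):
                    try:
                        pidx.append(states[p].index(lab))
                    except ValueError:
                        raise ParseError(
                            f"unknown state {lab!r} for parent {p!r}", row_line
                        ) from None
                if len(vals) != shape[0]:
                    raise ParseError(
                        f"row for {child!r} lists {len(vals)} values, expected {shape[0]}",
                        row_line,
                    )
                arr[(slice(None),) + tuple(pidx)] = vals
            if np.any(np.isnan(arr)):
                raise ParseError(
                    f"probability block for {child!r} is missing parent configurations",
                    line,
                )
            tables[child] = arr

    net = BayesianNetwork.from_cpt_arrays(
        states, parent_decl, tables, name=net_name or name_hint, check=False
    )
    _post_validate(net, strict=strict)
    return net


def _post_validate(net: BayesianNetwork, *, strict: bool) -> None:
    issues = net.validate(tol=1e-6)
    structural = [v for v in issues if v.kind != "normalization"]
    if structural:
        raise FormatError("; ".join(v.message for v in structural))
    soft = [v for v in issues if v.kind == "normalization"]
    if soft:
        msg = "; ".join(v.message for v in soft)
        if strict:
            raise FormatError(msg)
        warnings.warn(msg, stacklevel=3)


def read_bif(path, *, strict: bool = False) -> BayesianNetwork:
    """Read a Bayesian network from a BIF file."""
    p = Path(path)
    return loads_bif(p.read_text(), strict=strict, name_hint=p.stem)


_NAME_OK = re.compile(r"^[^\s{}()\[\]|,;]+$")


def _token_safe(name: str, fallback: str) -> str:
    return name if _NAME_OK.match(name) else fallback


def dumps_bif(net: BayesianNetwork) -> str:
    """Serialize a network to BIF text (deterministic, round-trip exact)."""
    out = [f"network {_token_safe(net.name, 'network')} {{", "}"]
    for v in net.variables:
        out.append(f"variable {v.name} {{")
        out.append(
            f"  type discrete [ {v.cardinality} ] {{ {', '.join(v.states)} }};"
        )
        out.append("}")
    for v in net.variables:
        parents = net.parents[v]
        cpt = net.cpts[v]
        perm = [cpt.variables.index(u) for u in (v,) + parents]
        arr = np.transpose(cpt.table, perm)
        if not parents:
            out.append(f"probability ( {v.name} ) {{")
            out.append(f"  table {', '.join(repr(float(x)) for x in arr)};")
        else:
            out.append(f"probability ( {v.name} | {', '.join(p.name for p in parents)} ) {{")
            pranges = [range(p.cardinality) for p in parents]
            import itertools

            for pidx in itertools.product(*pranges):
                labels = ", ".join(p.states[i] for p, i in zip(parents, pidx))
                vals = arr[(slice(None),) + pidx]
                out.append(
                    f"  ( {labels} ) {', '.join(repr(float(x)) for x in vals)};"
                )
        out.append("}")
    return "\n".join(out) + "\n"


def write_bif(net: BayesianNetwork, path) -> None:
    Path(path).write_text(dumps_bif(net))


# --------------------------------------------------------------- JSON dialect


def network_to_dict(net: BayesianNetwork) -> dict:
    """JSON-dialect representation: CPTs flat, row-major in canonical order."""
    return {
        "name": net.name,
        "variables": [{"name": v.name, "states": list(v.states)} for v in net.variables],
        "parents": {v.name: [p.name for p in net.parents[v]] for v in net.variables},
        "cpts": {v.name: net.cpts[v].table.ravel().tolist() for v in net.variables},
    }


def network_from_dict(obj: Mapping, *, strict: bool = False) -> BayesianNetwork:
    try:
        var_specs = obj["variables"]
        parent_spec = obj.get("parents", {})
        cpt_spec = obj["cpts"]
    except KeyError as e:
        raise FormatError(f"JSON network missing key {e.args[0]!r}") from None
    names = [d["name"] for d in var_specs]
    if len(set(names)) != len(names):
        raise FormatError("duplicate variable names in JSON network")
    variables = [
        Variable(d["name"], tuple(d["states"]), i) for i, d in enumerate(var_specs)
    ]
    by = {v.name: v for v in variables}
    parents: dict[Variable, tuple[Variable, ...]] = {}
    cpts: dict[Variable, Potential] = {}
    for v in variables:
        try:
            ps = tuple(by[p] for p in parent_spec.get(v.name, ()))
        except KeyError as e:
            raise FormatError(f"unknown parent {e.args[0]!r} of {v.name!r}") from None
        parents[v] = ps
        fam = canonical_scope((v,) + ps)
        if v.name not in cpt_spec:
            raise FormatError(f"missing CPT for {v.name!r}")
        flat = np.asarray(cpt_spec[v.name], dtype=float)
        try:
            cpts[v] = Potential(fam, flat)
        except ValueError as e:
            raise FormatError(f"CPT for {v.name!r}: {e}") from None
    net = BayesianNetwork(
        variables, parents, cpts, name=obj.get("name", "network"), check=False
    )
    _post_validate(net, strict=strict)
    return net


def read_json(path, *, strict: bool = False) -> BayesianNetwork:
    with open(path) as fh:
        return network_from_dict(json.load(fh), strict=strict)


def write_json(net: BayesianNetwork, path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_dict(net), fh, indent=1)
        fh.write("\n")


def read_network(path, *, strict: bool = False) -> BayesianNetwork:
    """Read BIF or JSON, dispatching on the file extension."""
    if str(path).endswith(".json"):
        return read_json(path, strict=strict)
    return read_bif(path, strict=strict)
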