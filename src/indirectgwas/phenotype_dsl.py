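"""A small expression language for phenotype definitions.

Phenotypes in observational-health data are rarely a single column: a study
case might be "anyone with an E11 diagnosis code OR an HbA1c measurement
>= 6.5".  This module parses such definitions — from an infix text grammar or
an equivalent JSON tree — into expression trees over feature columns, and
evaluates them row-wise against a phenotype matrix.

Operator set (10 operators):
    NOT                       unary boolean
    AND, OR, XOR              binary boolean ({0,1} operands)
    GT, GE, LT, LE, EQ        comparisons (return {0,1}; GE/LE inclusive)
    ADD                       arithmetic ``+``
plus feature leaves and numeric constants.

Boolean operators use the product forms AND = x*y, OR = x+y-xy, NOT = 1-x,
XOR = x+y-2xy.  On {0,1} data these are the exact truth tables; with
``fractional=True`` the same formulas accept values in [0,1], which is how
definitions are evaluated on microaggregated (centroid-valued) data.

The list interface (include / exclude code lists) lowers onto the same trees:
AND over included codes and NOT of excluded codes.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas_core import InputError

__all__ = [
    "PhenotypeNode",
    "ParseError",
    "parse_definition",
    "list_to_tree",
    "evaluate",
    "UNARY_OPS",
    "BINARY_OPS",
]

UNARY_OPS = frozenset({"NOT"})
BINARY_OPS = frozenset({"AND", "OR", "XOR", "GT", "GE", "LT", "LE", "EQ", "ADD"})
BOOLEAN_OPS = frozenset({"NOT", "AND", "OR", "XOR"})
_CMP_SYMBOL = {">": "GT", ">=": "GE", "<": "LT", "<=": "LE", "==": "EQ", "=": "EQ"}
_OP_SYMBOL = {"GT": ">", "GE": ">=", "LT": "<", "LE": "<=", "EQ": "==", "ADD": "+"}


class ParseError(InputError):
    """Malformed definition; carries the character position of the problem."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


@dataclass(frozen=True)
class PhenotypeNode:
    """One node of a phenotype expression tree.

    ``kind`` is ``"feature"`` (leaf referencing a column), ``"const"``
    (numeric leaf) or ``"op"``; operators carry 1 child (unary) or 2 (binary).
    """

    kind: str
    op: str | None = None
    children: tuple["PhenotypeNode", ...] = ()
    feature_id: str | None = None
    value: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "op":
            if self.op in UNARY_OPS and len(self.children) != 1:
                raise ParseError(f"{self.op} takes exactly 1 argument, got {len(self.children)}")
            if self.op in BINARY_OPS and len(self.children) != 2:
                raise ParseError(f"{self.op} takes exactly 2 arguments, got {len(self.children)}")
            if self.op not in UNARY_OPS | BINARY_OPS:
                raise ParseError(f"unknown operator {self.op!r}")
        elif self.kind == "feature":
            if not self.feature_id:
                raise ParseError("feature leaf needs a feature id")
        elif self.kind == "const":
            if self.value is None:
                raise ParseError("constant leaf needs a value")
        else:
            raise ParseError(f"unknown node kind {self.kind!r}")

    # -- constructors -------------------------------------------------------
    @staticmethod
    def feature(fid: str) -> "PhenotypeNode":
        return PhenotypeNode("feature", feature_id=fid)

    @staticmethod
    def const(v: float) -> "PhenotypeNode":
        return PhenotypeNode("const", value=float(v))

    @staticmethod
    def apply(op: str, *children: "PhenotypeNode") -> "PhenotypeNode":
        return PhenotypeNode("op", op=op.upper(), children=tuple(children))

    # -- traversal ----------------------------------------------------------
    def leaves(self) -> list[str]:
        """Feature ids referenced by the tree, in first-occurrence order."""
        out: list[str] = []

        def walk(n: "PhenotypeNode") -> None:
            if n.kind == "feature" and n.feature_id not in out:
                out.append(n.feature_id)
            for c in n.children:
                walk(c)

        walk(self)
        return out

    # -- serialization ------------------------------------------------------
    def to_text(self) -> str:
        """Canonical fully-parenthesized infix form; round-trips through parse."""
        if self.kind == "feature":
            return self.feature_id  # type: ignore[return-value]
        if self.kind == "const":
            v = self.value
            return repr(int(v)) if float(v).is_integer() else repr(v)
        if self.op == "NOT":
            return f"(NOT {self.children[0].to_text()})"
        a, b = (c.to_text() for c in self.children)
        sym = _OP_SYMBOL.get(self.op, self.op)
        return f"({a} {sym} {b})"

    def to_json(self) -> dict:
        if self.kind == "feature":
            return {"feature": self.feature_id}
        if self.kind == "const":
            return {"const": self.value}
        return {"op": self.op, "children": [c.to_json() for c in self.children]}

    @staticmethod
    def from_json(obj: dict) -> "PhenotypeNode":
        if "feature" in obj:
            return PhenotypeNode.feature(str(obj["feature"]))
        if "const" in obj:
            return PhenotypeNode.const(float(obj["const"]))
        if "op" in obj:
            kids = tuple(PhenotypeNode.from_json(c) for c in obj.get("children", []))
            return PhenotypeNode("op", op=str(obj["op"]).upper(), children=kids)
        raise ParseError(f"unrecognized JSON node: {obj!r}")


# ---------------------------------------------------------------------------
# Parser (infix text grammar)
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>\d+\.\d*|\.\d+|\d+)|(?P<id>[A-Za-z_][A-Za-z0-9_.]*)"
    r"|(?P<sym>>=|<=|==|>|<|=|\+|\(|\)|,))"
)

_KEYWORDS = {w: w for w in UNARY_OPS | BINARY_OPS}


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or m.end() == pos:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            raise ParseError(f"unexpected character {stripped[0]!r}", pos)
        if m.group("num"):
            tokens.append(("num", m.group("num"), m.start("num")))
        elif m.group("id"):
            word = m.group("id")
            kind = "kw" if word.upper() in _KEYWORDS else "id"
            tokens.append((kind, word, m.start("id")))
        else:
            tokens.append(("sym", m.group("sym"), m.start("sym")))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: list[tuple[str, str, int]], registry: set[str] | None):
        self.tokens = tokens
        self.i = 0
        self.registry = registry

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, None, None)

    def next(self):
        tok = self.peek()
        self.i += 1
        return tok

    def expect(self, value: str) -> None:
        kind, val, pos = self.peek()
        if val != value:
            raise ParseError(f"expected {value!r}, found {val!r}", pos)
        self.next()

    def parse(self) -> PhenotypeNode:
        node = self.or_expr()
        kind, val, pos = self.peek()
        if kind is not None:
            raise ParseError(f"unexpected trailing input {val!r}", pos)
        return node

    def or_expr(self) -> PhenotypeNode:
        node = self.xor_expr()
        while self.peek()[1] is not None and self.peek()[1].upper() == "OR":
            self.next()
            node = PhenotypeNode.apply("OR", node, self.xor_expr())
        return node

    def xor_expr(self) -> PhenotypeNode:
        node = self.and_expr()
        while self.peek()[1] is not None and self.peek()[1].upper() == "XOR":
            self.next()
            node = PhenotypeNode.apply("XOR", node, self.and_expr())
        return node

    def and_expr(self) -> PhenotypeNode:
        node = self.not_expr()
        while self.peek()[1] is not None and self.peek()[1].upper() == "AND":
            self.next()
            node = PhenotypeNode.apply("AND", node, self.not_expr())
        return node

    def not_expr(self) -> PhenotypeNode:
        kind, val, _ = self.peek()
        if kind == "kw" and val.upper() == "NOT" and not self._is_call():
            self.next()
            return PhenotypeNode.apply("NOT", self.not_expr())
        return self.cmp_expr()

    def cmp_expr(self) -> PhenotypeNode:
        node = self.add_expr()
        kind, val, _ = self.peek()
        if kind == "sym" and val in _CMP_SYMBOL:
            self.next()
            return PhenotypeNode.apply(_CMP_SYMBOL[val], node, self.add_expr())
        return node

    def add_expr(self) -> PhenotypeNode:
        node = self.primary()
        while self.peek()[1] == "+":
            self.next()
            node = PhenotypeNode.apply("ADD", node, self.primary())
        return node

    def _is_call(self) -> bool:
        nxt = self.tokens[self.i + 1] if self.i + 1 < len(self.tokens) else (None, None, None)
        return nxt[1] == "("

    def primary(self) -> PhenotypeNode:
        kind, val, pos = self.peek()
        if val == "(":
            self.next()
            node = self.or_expr()
            self.expect(")")
            return node
        if kind == "num":
            self.next()
            return PhenotypeNode.const(float(val))
        if kind == "kw" and self._is_call():
            # prefix call form: AND(x, y), NOT(x), GE(HbA1c, 6.5), ...
            op = val.upper()
            self.next()
            self.expect("(")
            args = [self.or_expr()]
            while self.peek()[1] == ",":
                self.next()
                args.append(self.or_expr())
            self.expect(")")
            want = 1 if op in UNARY_OPS else 2
            if len(args) != want:
                raise ParseError(f"{op} takes exactly {want} argument(s), got {len(args)}", pos)
            return PhenotypeNode.apply(op, *args)
        if kind == "id":
            self.next()
            if self.registry is not None and val not in self.registry:
                raise ParseError(f"unknown feature id {val!r}", pos)
            return PhenotypeNode.feature(val)
        if kind == "kw":
            raise ParseError(f"operator {val!r} used without operands", pos)
        raise ParseError("unexpected end of definition", pos)


def parse_definition(
    definition: str | dict, registry: set[str] | None = None
) -> PhenotypeNode:
    """Parse a phenotype definition from infix text or the JSON tree schema.

    ``registry``, when given, is the set of known feature ids; unresolvable
    leaves raise a :class:`ParseError` with the offending position (text form)
    or id (JSON form).
    """
    if isinstance(definition, dict):
        node = PhenotypeNode.from_json(definition)
    elif isinstance(definition, str) and definition.lstrip().startswith("{"):
        node = PhenotypeNode.from_json(json.loads(definition))
    else:
        tokens = _tokenize(definition)
        if not tokens:
            raise ParseError("empty definition")
        node = _Parser(tokens, registry).parse()
    if registry is not None:
        unknown = [f for f in node.leaves() if f not in registry]
        if unknown:
            raise ParseError(f"unknown feature ids: {unknown}")
    return node


def list_to_tree(included: list[str], excluded: list[str] | None = None) -> PhenotypeNode:
    """Lower an include/exclude code-list definition onto an expression tree.

    Result: AND over included leaves and NOT(excluded) leaves, left-associated.
    """
    excluded = excluded or []
    if not included:
        raise InputError("included code list must be non-empty")
    overlap = set(included) & set(excluded)
    if overlap:
        raise InputError(f"codes in both include and exclude lists: {sorted(overlap)}")
    terms = [PhenotypeNode.feature(f) for f in included]
    terms += [PhenotypeNode.apply("NOT", PhenotypeNode.feature(f)) for f in excluded]
    node = terms[0]
    for term in terms[1:]:
        node = PhenotypeNode.apply("AND", node, term)
    return node


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _check_boolean(values: np.ndarray, where: str, fractional: bool) -> None:
    if fractional:
        ok = np.all((values >= 0) & (values <= 1))
        msg = "values outside [0, 1]"
    else:
        ok = np.all((values == 0) | (values == 1))
        msg = "values not in {0, 1}"
    if not ok:
        raise InputError(
            f"boolean operator applied to non-binary operand {where!r}: {msg}. "
            "Use a comparison to binarize quantitative columns."
        )


def evaluate(
    node: PhenotypeNode,
    X: pd.DataFrame | np.ndarray,
    feature_ids: list[str] | None = None,
    fractional: bool = False,
) -> np.ndarray:
    """Evaluate a definition tree row-wise against a phenotype matrix.

    ``X`` is a DataFrame whose columns are feature ids, or an array paired
    with ``feature_ids``.  Boolean operators demand {0,1} operands unless
    ``fractional=True``, which admits [0,1] values (anonymized centroids) via
    the product formulas.  Comparisons are the bridge from quantitative
    columns to booleans and always return {0,1}.
    """
    if not isinstance(X, pd.DataFrame):
        if feature_ids is None:
            raise InputError("feature_ids required when X is a bare array")
        X = pd.DataFrame(np.asarray(X, dtype=float), columns=list(feature_ids))

    def rec(n: PhenotypeNode) -> np.ndarray:
        if n.kind == "feature":
            if n.feature_id not in X.columns:
                raise InputError(f"feature {n.feature_id!r} not present in the matrix")
            return X[n.feature_id].to_numpy(dtype=float)
        if n.kind == "const":
            return np.full(len(X), float(n.value))
        op = n.op
        if op in BOOLEAN_OPS:
            kids = []
            for c in n.children:
                v = rec(c)
                _check_boolean(v, c.to_text(), fractional)
                kids.append(v)
            if op == "NOT":
                return 1.0 - kids[0]
            x, y = kids
            if op == "AND":
                return x * y
            if op == "OR":
                return x + y - x * y
            return x + y - 2.0 * x * y  # XOR
        x, y = (rec(c) for c in n.children)
        if op == "ADD":
            return x + y
        if op == "GT":
            return (x > y).astype(float)
        if op == "GE":
            return (x >= y).astype(float)
        if op == "LT":
            return (x < y).astype(float)
        if op == "LE":
            return (x <= y).astype(float)
        if op == "EQ":
            return (x == y).astype(float)
        raise InputError(f"unknown operator {op!r}")

    return rec(node)
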