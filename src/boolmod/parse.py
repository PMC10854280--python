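"""Reading and writing Boolean networks as plain-text rule files.

The dialect is the widely used "target, factors" one (bnet-style): one line
per variable, a comma separating the variable name from a Boolean expression
over the operators ``!`` (not), ``&`` (and), ``|`` (or), parentheses, and the
constants ``0`` / ``1``.  Lines starting with ``#`` are comments.  Names that
appear only on the right-hand side are external parameters.

Expressions are parsed once and tabulated; update functions are stored as
truth tables and arity-reduced to their essential inputs (an audit record of
dropped inputs is kept on each function).
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

from .network import BooleanFunction, BooleanNetwork

_TOKEN_RE = re.compile(r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_]*)|(?P<op>[!&|()01]))")


class BnetSyntaxError(ValueError):
    """Raised on malformed rule text, with the offending line number."""


def _tokenize(text: str) -> list[str]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or m.end() == pos and not text[pos:].strip():
            break
        if not m.lastgroup:
            raise BnetSyntaxError(f"unexpected character {text[pos]!r}")
        tokens.append(m.group(m.lastgroup))
        pos = m.end()
    if text[pos:].strip():
        raise BnetSyntaxError(f"unexpected character {text[pos:].strip()[0]!r}")
    return tokens


class _Parser:
    """Recursive descent over:  expr := term ('|' term)* ;
    term := factor ('&' factor)* ; factor := '!' factor | '(' expr ')' |
    name | '0' | '1'."""

    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise BnetSyntaxError("unexpected end of expression")
        self.pos += 1
        return tok

    def parse(self):
        node = self.expr()
        if self.peek() is not None:
            raise BnetSyntaxError(f"trailing token {self.peek()!r}")
        return node

    def expr(self):
        node = self.term()
        while self.peek() == "|":
            self.take()
            node = ("or", node, self.term())
        return node

    def term(self):
        node = self.factor()
        while self.peek() == "&":
            self.take()
            node = ("and", node, self.factor())
        return node

    def factor(self):
        tok = self.take()
        if tok == "!":
            return ("not", self.factor())
        if tok == "(":
            node = self.expr()
            if self.take() != ")":
                raise BnetSyntaxError("expected ')'")
            return node
        if tok in ("0", "1"):
            return ("const", int(tok))
        if tok in ("&", "|", ")"):
            raise BnetSyntaxError(f"unexpected operator {tok!r}")
        return ("var", tok)


def _collect_names(node, acc: list[str]) -> None:
    kind = node[0]
    if kind == "var":
        if node[1] not in acc:
            acc.append(node[1])
    elif kind == "not":
        _collect_names(node[1], acc)
    elif kind in ("and", "or"):
        _collect_names(node[1], acc)
        _collect_names(node[2], acc)


def _eval_node(node, env: dict[str, int]) -> int:
    kind = node[0]
    if kind == "var":
        return env[node[1]]
    if kind == "const":
        return node[1]
    if kind == "not":
        return 1 - _eval_node(node[1], env)
    if kind == "and":
        return _eval_node(node[1], env) & _eval_node(node[2], env)
    return _eval_node(node[1], env) | _eval_node(node[2], env)


def parse_expression(
    text: str, inputs: Sequence[str] | None = None, reduce: bool = True
) -> BooleanFunction:
    """Tabulate a Boolean expression into a :class:`BooleanFunction`.

    ``inputs`` optionally fixes the input list (a superset of the names used);
    otherwise inputs are the names in order of first appearance.  With
    ``reduce`` the result is arity-reduced to essential inputs.
    """
    node = _Parser(_tokenize(text)).parse()
    names: list[str] = []
    _collect_names(node, names)
    if inputs is not None:
        missing = [v for v in names if v not in inputs]
        if missing:
            raise ValueError(f"expression uses undeclared inputs: {missing}")
        names = list(inputs)
    m = len(names)
    table = []
    for idx in range(1 << m):
        env = {v: (idx >> (m - 1 - i)) & 1 for i, v in enumerate(names)}
        table.append(_eval_node(node, env))
    f = BooleanFunction(names, table)
    return f.reduced() if reduce else f


def parse_rules(text: str) -> BooleanNetwork:
    """Parse "target, expression" rule text into a Boolean network."""
    variables: list[str] = []
    raw: dict[str, str] = {}
    lines: dict[str, int] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        # tolerate a "targets, factors" header line
        if lineno == 1 and re.fullmatch(
            r"targets?\s*,\s*factors?", stripped, flags=re.IGNORECASE
        ):
            continue
        if "," not in stripped:
            raise BnetSyntaxError(
                f"line {lineno}: expected 'target, expression', got {stripped!r}"
            )
        target, expr = stripped.split(",", 1)
        target = target.strip()
        if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", target):
            raise BnetSyntaxError(f"line {lineno}: invalid target name {target!r}")
        if target in raw:
            raise BnetSyntaxError(
                f"line {lineno}: duplicate rule for {target!r} "
                f"(first defined on line {lines[target]})"
            )
        if not expr.strip():
            raise BnetSyntaxError(f"line {lineno}: empty expression for {target!r}")
        variables.append(target)
        raw[target] = expr
        lines[target] = lineno

    functions: dict[str, BooleanFunction] = {}
    externals: list[str] = []
    for target in variables:
        try:
            f = parse_expression(raw[target])
        except (BnetSyntaxError, ValueError) as exc:
            raise BnetSyntaxError(f"line {lines[target]}: {exc}") from None
        functions[target] = f
        for name in f.inputs:
            if name not in raw and name not in externals:
                externals.append(name)
    if not variables:
        raise BnetSyntaxError("no rules found")
    return BooleanNetwork(variables, functions, externals)


def read_network(path) -> BooleanNetwork:
    """Read a rule file from disk."""
    with open(path, "r", encoding="utf-8") as fh:
        return parse_rules(fh.read())


def expression_of(f: BooleanFunction) -> str:
    """Render a truth table as a disjunctive-normal-form expression."""
    f = f.reduced()
    if f.is_constant:
        return str(f.table[0])
    m = f.arity
    terms = []
    for idx in range(1 << m):
        if not f.table[idx]:
            continue
        lits = []
        for i, v in enumerate(f.inputs):
            bit = (idx >> (m - 1 - i)) & 1
            lits.append(v if bit else f"!{v}")
        terms.append(" & ".join(lits) if len(lits) == 1 else "(" + " & ".join(lits) + ")")
    return " | ".join(terms)


def write_rules(network: BooleanNetwork) -> str:
    """Render a network as rule text; ``parse_rules(write_rules(N))`` is
    truth-table identical to ``N``."""
    out = []
    for v in network.variables:
        out.append(f"{v}, {expression_of(network.functions[v])}")
    return "\n".join(out) + "\n"


def write_network(network: BooleanNetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_rules(network))
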