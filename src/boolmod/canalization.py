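"""Canalizing structure of Boolean functions: layers, depth, core polynomial.

A variable x_i canalizes f when one input value a forces the output to b
regardless of every other input.  Stripping all canalizing variables and
restricting to the non-canalizing branch exposes further variables that
"become" canalizing; iterating yields the unique stratification of any
non-constant Boolean function into an extended monomial form

    f = M_1 ( M_2 ( ... ( M_{r-1} ( M_r * p_C + 1 ) + 1 ) ... ) + 1 ) + q

over GF(2), where each layer M_i = prod_j (x_ij + a_ij) is a nonconstant
extended monomial that vanishes exactly when one of its variables receives
its canalizing input, p_C is the core polynomial on the variables that never
canalize, and q in {0,1}.  The canalized output of layer i is b_i = q + i - 1
(mod 2): outputs strictly alternate, variables within a layer share their
output, and the layer structure (k_1, ..., k_r) lists the layer sizes.  The
canalizing depth is k = sum k_i; f is nested canalizing (NCF) iff k equals
the number of essential variables, in which case p_C == 1.

Uniqueness requires two exceptional-case conventions: if p_C == 1 and r != 1
then k_r >= 2 (a final singleton layer would merge into the layer above),
and if p_C == 1, r = 1, k_1 = 1 then q = 0 (fixing the orientation of the
two equivalent write-ups of f = x + c).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .network import BooleanFunction

ARITY_CAP = 16  # layer extraction is exponential in arity; biological rules are small


class ConstantFunctionError(ValueError):
    """Canalization is undefined for constant functions."""


def _check_input(f: BooleanFunction) -> BooleanFunction:
    if f.arity > ARITY_CAP:
        raise ValueError(
            f"arity {f.arity} exceeds the supported cap of {ARITY_CAP}; "
            f"layer extraction is exponential in arity"
        )
    f = f.reduced()
    if f.is_constant:
        raise ConstantFunctionError(
            "canalizing structure is undefined for constant functions"
        )
    return f


def canalizing_variables(f: BooleanFunction) -> list[tuple[str, int, int]]:
    """All triples (variable, canalizing input a, canalized output b) with
    f == b whenever the variable equals a.

    Non-essential inputs are ignored.  A function with a single essential
    variable satisfies the definition for both input values; both triples are
    returned here (the layer decomposition disambiguates them).
    """
    f = _check_input(f)
    out = []
    for v in f.inputs:
        for a in (0, 1):
            g = f.restrict(v, a)
            if g.is_constant:
                out.append((v, a, g.table[0]))
    return out


@dataclass(frozen=True)
class CanalizingLayers:
    """The unique extended monomial form of a non-constant Boolean function.

    ``layers[i]`` lists (variable, canalizing input) pairs of layer i+1, in
    original input order; ``outputs[i]`` is that layer's canalized output.
    ``core`` is the core polynomial p_C on the never-canalizing variables (a
    constant-1 function when f is nested canalizing) and ``q`` the additive
    constant of the form.
    """

    layers: tuple[tuple[tuple[str, int], ...], ...]
    outputs: tuple[int, ...]
    core: BooleanFunction
    q: int

    @property
    def depth(self) -> int:
        return sum(len(layer) for layer in self.layers)

    @property
    def structure(self) -> tuple[int, ...]:
        return tuple(len(layer) for layer in self.layers)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def is_nested_canalizing(self) -> bool:
        return self.core.arity == 0 and self.n_layers > 0

    def layer_of(self, variable: str) -> int:
        """1-based layer index of a variable; r+1 if it sits in the core."""
        for i, layer in enumerate(self.layers, start=1):
            if any(v == variable for v, _ in layer):
                return i
        if variable in self.core.inputs:
            return self.n_layers + 1
        raise KeyError(f"{variable!r} is not an essential variable of this function")

    def canalizing_input(self, variable: str) -> int:
        for layer in self.layers:
            for v, a in layer:
                if v == variable:
                    return a
        raise KeyError(f"{variable!r} is not in any canalizing layer")

    def variables(self) -> tuple[str, ...]:
        """All essential variables, layer variables first."""
        out = [v for layer in self.layers for v, _ in layer]
        out.extend(self.core.inputs)
        return tuple(out)


def layer_decomposition(f: BooleanFunction) -> CanalizingLayers:
    """Compute the unique layer decomposition by iterated stripping.

    Each round collects every canalizing variable of the current function
    (they form one layer and provably share one output), then restricts to
    the branch where none of them received its canalizing input.  Remaining
    variables form the core.
    """
    f = _check_input(f)
    current = f
    layers: list[tuple[tuple[str, int], ...]] = []
    outputs: list[int] = []
    while not current.is_constant:
        found: list[tuple[str, int, int]] = []
        for v in current.inputs:
            for a in (0, 1):
                g = current.restrict(v, a)
                if g.is_constant:
                    found.append((v, a, g.table[0]))
        if not found:
            break
        if current.arity == 1:
            # both orientations of f = x + c satisfy the definition; the
            # exceptional-case convention q = 0 selects output 0
            found = [t for t in found if t[2] == 0]
        outs = {b for _, _, b in found}
        if len(outs) != 1:
            raise AssertionError(
                f"canalizing variables of one layer disagree on the output: {found}"
            )
        layers.append(tuple((v, a) for v, a, _ in found))
        outputs.append(outs.pop())
        for v, a, _ in found:
            current = current.restrict(v, 1 - a)
    r = len(layers)
    if r == 0:
        return CanalizingLayers(layers=(), outputs=(), core=f, q=0)
    q = outputs[0]
    # with no layer triggered, f evaluates to p_C + (r - 1) + q over GF(2)
    parity = (r - 1 + q) % 2
    core = current.negate() if parity else current
    if core.arity == 0 and core.table[0] != 1:
        raise AssertionError("core of a nested canalizing function must be 1")
    return CanalizingLayers(
        layers=tuple(layers), outputs=tuple(outputs), core=core, q=q
    )


def layer_structure(f: BooleanFunction) -> tuple[int, ...]:
    """Layer sizes (k_1, ..., k_r); empty for non-canalizing functions."""
    return layer_decomposition(f).structure


def canalizing_depth(f: BooleanFunction) -> int:
    return layer_decomposition(f).depth


def is_nested_canalizing(f: BooleanFunction) -> bool:
    """True iff every essential variable eventually canalizes."""
    return layer_decomposition(f).is_nested_canalizing


def reconstruct(
    layers: CanalizingLayers, variable_order: Sequence[str] | None = None
) -> BooleanFunction:
    """Tabulate the extended monomial form back into a truth table.

    Round-tripping ``reconstruct(layer_decomposition(f))`` reproduces f
    exactly (on its essential variables), which is the executable form of the
    uniqueness statement.
    """
    order = tuple(variable_order) if variable_order is not None else layers.variables()
    if set(order) != set(layers.variables()):
        raise ValueError("variable_order must cover exactly the decomposed variables")
    r = layers.n_layers

    def fn(*bits: int) -> int:
        env = dict(zip(order, bits))
        if r == 0:
            return layers.core(env)
        mono = [
            int(all(env[v] != a for v, a in layer)) for layer in layers.layers
        ]
        g = mono[r - 1] * (layers.core(env) if layers.core.arity else layers.core.table[0])
        for i in range(r - 2, -1, -1):
            g = mono[i] * ((g + 1) % 2)
        return (g + layers.q) % 2

    return BooleanFunction.from_callable(order, fn)


def random_ncf(
    arity: int,
    structure: Sequence[int] | None = None,
    seed: int | np.random.Generator | None = None,
    variables: Sequence[str] | None = None,
) -> BooleanFunction:
    """Draw a random nested canalizing function with a prescribed layer
    structure (canalizing inputs, layer membership and the constant q are
    randomized; the recovered structure of the result is exactly the request).

    A structure is valid when its parts are positive, sum to ``arity`` and —
    because an NCF has core 1 — its last layer has size >= 2 whenever there
    is more than one layer.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if arity < 1:
        raise ValueError("arity must be >= 1")
    if variables is None:
        variables = tuple(f"x{i+1}" for i in range(arity))
    variables = tuple(variables)
    if len(variables) != arity:
        raise ValueError("need exactly one variable name per input")
    if structure is None:
        structure = _random_structure(arity, rng)
    structure = tuple(int(k) for k in structure)
    if any(k < 1 for k in structure) or sum(structure) != arity:
        raise ValueError(f"structure {structure} is not a composition of {arity}")
    if len(structure) > 1 and structure[-1] < 2:
        raise ValueError(
            f"structure {structure} is invalid for a nested canalizing function: "
            f"with core 1 the last layer must have size >= 2"
        )
    perm = [variables[i] for i in rng.permutation(arity)]
    layers = []
    pos = 0
    for k in structure:
        members = sorted(perm[pos : pos + k], key=variables.index)
        layers.append(tuple((v, int(rng.integers(2))) for v in members))
        pos += k
    q = 0 if arity == 1 else int(rng.integers(2))
    outputs = tuple((q + i) % 2 for i in range(len(structure)))
    decomp = CanalizingLayers(
        layers=tuple(layers),
        outputs=outputs,
        core=BooleanFunction.constant(1),
        q=q,
    )
    return reconstruct(decomp, variables)


def _random_structure(arity: int, rng: np.random.Generator) -> tuple[int, ...]:
    """A uniform-ish random valid NCF layer structure for ``arity`` inputs."""
    if arity == 1:
        return (1,)
    parts: list[int] = []
    left = arity
    while left > 0:
        if left <= 3:
            parts.append(left)
            break
        k = int(rng.integers(1, left))
        if left - k == 1:  # would force a trailing singleton layer
            k = left
        parts.append(k)
        left -= k
    if len(parts) > 1 and parts[-1] < 2:
        parts[-2] += parts[-1]
        parts.pop()
    return tuple(parts)
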