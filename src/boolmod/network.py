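"""Synchronous Boolean networks: functions, states, trajectories, attractors.

A Boolean network on n ordered variables is a map F = (f_1, ..., f_n) from
{0,1}^n to itself; every variable is updated simultaneously.  Each coordinate
function is stored as a truth table over its own ordered input list, which may
reference network variables or external parameters (inputs a module receives
from outside, with no update rule of their own).

Bit-order convention used throughout the package: the first variable is the
leftmost character of a printed state string and the most significant bit of
an integer state index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx

DEFAULT_ENUMERATION_CAP = 24

State = tuple[int, ...]


def parse_state(text: str) -> State:
    """Parse a left-to-right bit string such as ``"010"`` into a state tuple."""
    if not text or any(c not in "01" for c in text):
        raise ValueError(f"not a bit string: {text!r}")
    return tuple(int(c) for c in text)


def state_to_str(state: Sequence[int]) -> str:
    return "".join(str(b) for b in state)


def _state_to_index(state: Sequence[int]) -> int:
    idx = 0
    for b in state:
        idx = (idx << 1) | b
    return idx


def _index_to_state(idx: int, n: int) -> State:
    return tuple((idx >> (n - 1 - i)) & 1 for i in range(n))


class BooleanFunction:
    """A Boolean function of named inputs, stored as a canonical truth table.

    ``table[i]`` is the output for the input combination whose bits, read in
    input-list order, form the binary expansion of ``i`` (first input = most
    significant bit).  ``removed_inputs`` records inputs that were listed at
    construction time but dropped because they turned out to be non-essential.
    """

    __slots__ = ("inputs", "table", "removed_inputs")

    def __init__(
        self,
        inputs: Sequence[str],
        table: Sequence[int],
        removed_inputs: Sequence[str] = (),
    ):
        inputs = tuple(inputs)
        table = tuple(int(v) for v in table)
        if len(set(inputs)) != len(inputs):
            raise ValueError(f"duplicate input names: {inputs}")
        if len(table) != 1 << len(inputs):
            raise ValueError(
                f"table has {len(table)} entries; expected {1 << len(inputs)}"
            )
        if any(v not in (0, 1) for v in table):
            raise ValueError("truth table entries must be 0 or 1")
        self.inputs = inputs
        self.table = table
        self.removed_inputs = tuple(removed_inputs)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_callable(
        cls, inputs: Sequence[str], fn: Callable[..., int]
    ) -> "BooleanFunction":
        m = len(inputs)
        table = []
        for idx in range(1 << m):
            bits = _index_to_state(idx, m)
            table.append(int(bool(fn(*bits))))
        return cls(inputs, table)

    @classmethod
    def constant(cls, value: int) -> "BooleanFunction":
        return cls((), (int(value),))

    # -- basic queries -----------------------------------------------------

    @property
    def arity(self) -> int:
        return len(self.inputs)

    @property
    def is_constant(self) -> bool:
        return len(set(self.table)) == 1

    def eval_bits(self, bits: Sequence[int]) -> int:
        if len(bits) != self.arity:
            raise ValueError(f"expected {self.arity} bits, got {len(bits)}")
        return self.table[_state_to_index(bits)]

    def __call__(self, values: Mapping[str, int]) -> int:
        try:
            bits = [values[name] for name in self.inputs]
        except KeyError as exc:
            raise KeyError(f"no value provided for input {exc.args[0]!r}") from None
        return self.eval_bits(bits)

    # -- structural operations --------------------------------------------

    def restrict(self, variable: str, value: int) -> "BooleanFunction":
        """Fix one input to a constant, removing it from the input list."""
        if variable not in self.inputs:
            raise ValueError(f"{variable!r} is not an input of this function")
        pos = self.inputs.index(variable)
        m = self.arity
        new_inputs = self.inputs[:pos] + self.inputs[pos + 1 :]
        table = []
        for idx in range(1 << (m - 1)):
            bits = list(_index_to_state(idx, m - 1))
            bits.insert(pos, value)
            table.append(self.eval_bits(bits))
        return BooleanFunction(new_inputs, table)

    def pin(self, variable: str, value: int) -> "BooleanFunction":
        """Fix one input to a constant but keep it listed (it becomes
        non-essential).  This is the truth-table form of an active edge
        control."""
        if variable not in self.inputs:
            raise ValueError(f"{variable!r} is not an input of this function")
        pos = self.inputs.index(variable)
        m = self.arity
        table = []
        for idx in range(1 << m):
            bits = list(_index_to_state(idx, m))
            bits[pos] = value
            table.append(self.eval_bits(bits))
        return BooleanFunction(self.inputs, table)

    def is_essential_in(self, variable: str) -> bool:
        """True iff toggling ``variable`` changes the output for some input."""
        if variable not in self.inputs:
            raise ValueError(f"{variable!r} is not an input of this function")
        pos = self.inputs.index(variable)
        m = self.arity
        shift = m - 1 - pos
        for idx in range(1 << m):
            if (idx >> shift) & 1 == 0:
                if self.table[idx] != self.table[idx | (1 << shift)]:
                    return True
        return False

    def essential_inputs(self) -> tuple[str, ...]:
        return tuple(v for v in self.inputs if self.is_essential_in(v))

    def reduced(self) -> "BooleanFunction":
        """Drop non-essential inputs, recording them in ``removed_inputs``."""
        f = self
        removed = list(self.removed_inputs)
        for v in self.inputs:
            if not f.is_essential_in(v):
                f = f.restrict(v, 0)
                removed.append(v)
        if not removed:
            return self
        return BooleanFunction(f.inputs, f.table, removed_inputs=removed)

    def rename_inputs(self, mapping: Mapping[str, str]) -> "BooleanFunction":
        new = tuple(mapping.get(v, v) for v in self.inputs)
        return BooleanFunction(new, self.table, self.removed_inputs)

    def negate(self) -> "BooleanFunction":
        return BooleanFunction(
            self.inputs, tuple(1 - v for v in self.table), self.removed_inputs
        )

    def equivalent_to(self, other: "BooleanFunction") -> bool:
        """Truth-table equality as functions of named inputs (input order and
        non-essential inputs are ignored)."""
        a, b = self.reduced(), other.reduced()
        if set(a.inputs) != set(b.inputs):
            return False
        order = sorted(a.inputs)
        m = len(order)
        for idx in range(1 << m):
            env = dict(zip(order, _index_to_state(idx, m)))
            if a(env) != b(env):
                return False
        return True

    def __eq__(self, other) -> bool:
        if not isinstance(other, BooleanFunction):
            return NotImplemented
        return self.inputs == other.inputs and self.table == other.table

    def __hash__(self) -> int:
        return hash((self.inputs, self.table))

    def __repr__(self) -> str:
        return f"BooleanFunction({list(self.inputs)}, table={''.join(map(str, self.table))})"


@dataclass(frozen=True)
class Attractor:
    """An ordered, cyclically-mapped sequence of states.

    For autonomous networks the states are distinct and ``F`` maps each state
    to the next; a length-1 attractor is a steady state.  For non-autonomous
    (driven) modules the same module state may legitimately recur within one
    period, so distinctness is not enforced.  The stored rotation is
    canonical: the lexicographically smallest rotation of the sequence.
    """

    states: tuple[State, ...]

    def __post_init__(self):
        if not self.states:
            raise ValueError("attractor must contain at least one state")
        object.__setattr__(self, "states", canonical_rotation(self.states))

    @property
    def length(self) -> int:
        return len(self.states)

    @property
    def is_steady_state(self) -> bool:
        return len(self.states) == 1

    def __str__(self) -> str:
        return "{" + ",".join(state_to_str(s) for s in self.states) + "}"

    __repr__ = __str__


def canonical_rotation(states: Sequence[State]) -> tuple[State, ...]:
    seq = [tuple(s) for s in states]
    rotations = [tuple(seq[i:] + seq[:i]) for i in range(len(seq))]
    return min(rotations)


def minimal_period(states: Sequence[State]) -> tuple[State, ...]:
    """Reduce a periodic sequence to one minimal period."""
    seq = [tuple(s) for s in states]
    n = len(seq)
    for p in range(1, n + 1):
        if n % p == 0 and all(seq[i] == seq[i % p] for i in range(n)):
            return tuple(seq[:p])
    return tuple(seq)


@dataclass
class Trajectory:
    """A forward orbit up to (and excluding) the second visit of a state."""

    states: list[State]
    transient_length: int
    period: int


class BooleanNetwork:
    """An ordered collection of update functions, one per variable.

    ``externals`` lists parameter names that appear as function inputs but are
    not updated; a network with no externals is autonomous and defines a map
    {0,1}^n -> {0,1}^n.
    """

    def __init__(
        self,
        variables: Sequence[str],
        functions: Mapping[str, BooleanFunction],
        externals: Sequence[str] = (),
    ):
        variables = tuple(variables)
        externals = tuple(externals)
        if len(set(variables)) != len(variables):
            raise ValueError("duplicate variable names")
        if len(set(externals)) != len(externals):
            raise ValueError("duplicate external parameter names")
        if set(variables) & set(externals):
            raise ValueError(
                f"names used both as variable and external: "
                f"{sorted(set(variables) & set(externals))}"
            )
        missing = set(variables) - set(functions)
        if missing:
            raise ValueError(f"no update function for: {sorted(missing)}")
        known = set(variables) | set(externals)
        for v in variables:
            for inp in functions[v].inputs:
                if inp not in known:
                    raise ValueError(
                        f"function of {v!r} reads {inp!r}, which is neither a "
                        f"variable nor a declared external parameter"
                    )
        self.variables = variables
        self.functions = {v: functions[v] for v in variables}
        self.externals = externals

    # -- basic queries -----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.variables)

    @property
    def is_autonomous(self) -> bool:
        return not self.externals

    def with_function(self, variable: str, f: BooleanFunction) -> "BooleanNetwork":
        funcs = dict(self.functions)
        funcs[variable] = f
        return BooleanNetwork(self.variables, funcs, self.externals)

    def reduced(self) -> "BooleanNetwork":
        """Arity-reduce every update function to its essential inputs."""
        return BooleanNetwork(
            self.variables,
            {v: f.reduced() for v, f in self.functions.items()},
            self.externals,
        )

    def bind(self, bindings: Mapping[str, int] | None) -> "BooleanNetwork":
        """Substitute constant values for all external parameters."""
        bindings = dict(bindings or {})
        missing = [e for e in self.externals if e not in bindings]
        if missing:
            raise ValueError(f"unbound external parameter(s): {missing}")
        if not self.externals:
            return self
        funcs = {}
        for v, f in self.functions.items():
            for e in self.externals:
                if e in f.inputs:
                    f = f.restrict(e, bindings[e])
            funcs[v] = f
        return BooleanNetwork(self.variables, funcs, ())

    def equivalent_to(self, other: "BooleanNetwork") -> bool:
        """Same variables (as a set) with truth-table-equal update functions."""
        if set(self.variables) != set(other.variables):
            return False
        return all(
            self.functions[v].equivalent_to(other.functions[v])
            for v in self.variables
        )

    def __repr__(self) -> str:
        ext = f", externals={list(self.externals)}" if self.externals else ""
        return f"BooleanNetwork({list(self.variables)}{ext})"

    # -- fast enumeration support ------------------------------------------

    def _successor_fn(self) -> Callable[[int], int]:
        """Integer-indexed successor map for an autonomous network."""
        if not self.is_autonomous:
            raise ValueError(
                "network has unbound external parameters: "
                f"{list(self.externals)}; bind them first"
            )
        n = self.n
        pos = {v: i for i, v in enumerate(self.variables)}
        compiled = []
        for v in self.variables:
            f = self.functions[v]
            shifts = tuple(n - 1 - pos[inp] for inp in f.inputs)
            compiled.append((shifts, f.table))

        def successor(s: int) -> int:
            out = 0
            for shifts, table in compiled:
                idx = 0
                for sh in shifts:
                    idx = (idx << 1) | ((s >> sh) & 1)
                out = (out << 1) | table[idx]
            return out

        return successor


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def evaluate(
    network: BooleanNetwork,
    state: Sequence[int],
    bindings: Mapping[str, int] | None = None,
) -> State:
    """One synchronous update step: return F(x)."""
    state = tuple(state)
    if len(state) != network.n:
        raise ValueError(f"state has {len(state)} bits; network has {network.n}")
    env = dict(zip(network.variables, state))
    bindings = bindings or {}
    for e in network.externals:
        if e not in bindings:
            raise ValueError(f"unbound external parameter: {e!r}")
        env[e] = bindings[e]
    return tuple(network.functions[v](env) for v in network.variables)


def trajectory(
    network: BooleanNetwork,
    initial: Sequence[int],
    bindings: Mapping[str, int] | None = None,
) -> Trajectory:
    """Iterate F from ``initial`` until a state repeats; the finite state
    space guarantees termination within 2^n steps."""
    seen: dict[State, int] = {}
    states: list[State] = []
    x = tuple(initial)
    while x not in seen:
        seen[x] = len(states)
        states.append(x)
        x = evaluate(network, x, bindings)
    first = seen[x]
    return Trajectory(states=states, transient_length=first, period=len(states) - first)


def is_essential(f: BooleanFunction, variable: str) -> bool:
    return f.is_essential_in(variable)


@dataclass(frozen=True)
class WiringDiagram:
    """Directed dependency graph: an edge x_i -> x_j iff f_j is essential in
    x_i.  Nodes are the network variables (external parameters excluded)."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


def wiring_diagram(network: BooleanNetwork) -> WiringDiagram:
    var_set = set(network.variables)
    edges = []
    for target in network.variables:
        f = network.functions[target]
        for src in f.inputs:
            if src in var_set and f.is_essential_in(src):
                edges.append((src, target))
    return WiringDiagram(nodes=network.variables, edges=tuple(edges))


def _check_cap(n: int, cap: int) -> None:
    if n > cap:
        raise ValueError(
            f"exhaustive enumeration over 2^{n} states exceeds the cap of "
            f"2^{cap}; raise the cap explicitly or use the modular route "
            f"(decompose the network and work module by module)"
        )


def state_space(
    network: BooleanNetwork,
    bindings: Mapping[str, int] | None = None,
    cap: int = DEFAULT_ENUMERATION_CAP,
) -> nx.DiGraph:
    """The functional graph on all 2^n states (each node has out-degree 1).

    Nodes are bit strings in variable order, e.g. ``"010"``.
    """
    net = network.bind(bindings) if network.externals or bindings else network
    _check_cap(net.n, cap)
    succ = net._successor_fn()
    n = net.n
    g = nx.DiGraph()
    for s in range(1 << n):
        g.add_edge(
            state_to_str(_index_to_state(s, n)),
            state_to_str(_index_to_state(succ(s), n)),
        )
    g.add_nodes_from(
        state_to_str(_index_to_state(s, n)) for s in range(1 << n)
    )
    return g


def attractors(
    network: BooleanNetwork,
    bindings: Mapping[str, int] | None = None,
    cap: int = DEFAULT_ENUMERATION_CAP,
) -> list[Attractor]:
    """All attractors (minimal sets C with F(C) = C), by exhaustive
    enumeration of the functional graph.

    Returned sorted by (length, first state) for deterministic output.
    """
    net = network.bind(bindings) if network.externals or bindings else network
    _check_cap(net.n, cap)
    n = net.n
    succ = net._successor_fn()
    size = 1 << n
    color = bytearray(size)  # 0 = unvisited, 1 = done
    found: list[Attractor] = []
    for start in range(size):
        if color[start]:
            continue
        path: list[int] = []
        pos: dict[int, int] = {}
        cur = start
        while not color[cur] and cur not in pos:
            pos[cur] = len(path)
            path.append(cur)
            cur = succ(cur)
        if cur in pos:  # new cycle discovered
            cycle = path[pos[cur] :]
            found.append(
                Attractor(tuple(_index_to_state(s, n) for s in cycle))
            )
        for s in path:
            color[s] = 1
    found.sort(key=lambda a: (a.length, a.states))
    return found


def basin_of(
    network: BooleanNetwork,
    attractor: Attractor,
    bindings: Mapping[str, int] | None = None,
) -> set[State]:
    """All states whose trajectory ends in ``attractor``."""
    net = network.bind(bindings) if network.externals or bindings else network
    members = set(attractor.states)
    basin = set()
    for s in range(1 << net.n):
        x = _index_to_state(s, net.n)
        t = trajectory(net, x)
        if t.states[t.transient_length] in members:
            basin.add(x)
    return basin
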