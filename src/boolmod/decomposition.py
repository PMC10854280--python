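"""Modular decomposition of Boolean networks and compositional dynamics.

The wiring diagram of any Boolean network splits into strongly connected
components (SCCs) whose mutual connections run in one direction only.  The
*modules* of the network are its restrictions to the SCC variable sets; each
module is itself a Boolean network whose cross-module inputs become external
parameters.  Contracting every SCC yields an acyclic quotient digraph, and
the network is recovered from its modules by iterated semidirect products
along a topological order.

The dynamics decompose accordingly: an attractor of the full network is a
direct sum C1 (+) C2 of an attractor of the upstream module and an attractor
of the downstream module driven by the periodic input sequence C1 induces.
Driven (non-autonomous) attractors are computed here on the product space of
drive phase and module state.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx

from .network import (
    DEFAULT_ENUMERATION_CAP,
    Attractor,
    BooleanFunction,
    BooleanNetwork,
    State,
    _index_to_state,
    attractors,
    canonical_rotation,
    evaluate,
    minimal_period,
    wiring_diagram,
)

EXTERNAL_PREFIX = "e_"


def external_name(variable: str) -> str:
    """Deterministic name of the external parameter standing in for an
    out-of-module input."""
    return EXTERNAL_PREFIX + variable


def external_source(name: str) -> str:
    """Inverse of :func:`external_name`."""
    if not name.startswith(EXTERNAL_PREFIX):
        raise ValueError(f"{name!r} does not follow the {EXTERNAL_PREFIX}<var> convention")
    return name[len(EXTERNAL_PREFIX) :]


@dataclass(frozen=True)
class Coupling:
    """Injective map from upstream variable names to external-parameter names
    of a downstream module."""

    map: tuple[tuple[str, str], ...]

    @classmethod
    def from_dict(cls, d: Mapping[str, str]) -> "Coupling":
        items = tuple(sorted(d.items()))
        if len(set(v for _, v in items)) != len(items):
            raise ValueError("coupling must be injective")
        return cls(items)

    def as_dict(self) -> dict[str, str]:
        return dict(self.map)

    def __len__(self) -> int:
        return len(self.map)


@dataclass
class ModularDecomposition:
    """SCC modules of a network, their couplings, and the quotient DAG.

    Modules are numbered 0..m-1 in a topological order of the quotient DAG
    (ties broken by smallest original variable index, so the numbering is
    reproducible).  ``couplings[(i, j)]`` maps module-i variables onto the
    externals they feed in module j.
    """

    network: BooleanNetwork
    modules: list[BooleanNetwork]
    variable_sets: list[tuple[str, ...]]
    quotient_dag: nx.DiGraph
    order: tuple[int, ...]
    couplings: dict[tuple[int, int], Coupling]

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def module_of(self, variable: str) -> int:
        for i, s in enumerate(self.variable_sets):
            if variable in s:
                return i
        raise KeyError(f"unknown variable {variable!r}")

    def nontrivial_modules(self) -> list[int]:
        """Indices of modules with more than one variable."""
        return [i for i, s in enumerate(self.variable_sets) if len(s) > 1]


@dataclass
class DrivenModule:
    """A module with external parameters under a periodic drive g(t).

    ``drive`` is one period of external-value bindings; ``drive[t]`` must
    cover every external parameter of the module.
    """

    module: BooleanNetwork
    drive: tuple[Mapping[str, int], ...]

    def __post_init__(self):
        if not self.drive:
            raise ValueError("drive must have period >= 1")
        for t, g in enumerate(self.drive):
            missing = [e for e in self.module.externals if e not in g]
            if missing:
                raise ValueError(
                    f"drive at phase {t} leaves externals unbound: {missing}"
                )


# ---------------------------------------------------------------------------
# Structure
# ---------------------------------------------------------------------------


def restriction(network: BooleanNetwork, variable_subset: Sequence[str]) -> BooleanNetwork:
    """Restrict a network to a subset of its variables.

    The subset keeps its original update functions; inputs from outside the
    subset become external parameters named ``e_<variable>``.  External
    parameters of the parent network are carried over unchanged.
    """
    subset = list(variable_subset)
    if not subset:
        raise ValueError("variable subset must be nonempty")
    unknown = [v for v in subset if v not in network.variables]
    if unknown:
        raise ValueError(f"unknown variable(s): {unknown}")
    ordered = tuple(v for v in network.variables if v in set(subset))
    keep = set(ordered)
    funcs: dict[str, BooleanFunction] = {}
    externals: list[str] = []
    for v in ordered:
        f = network.functions[v].reduced()
        renaming = {}
        for inp in f.inputs:
            if inp in keep:
                continue
            if inp in network.externals:
                if inp not in externals:
                    externals.append(inp)
                continue
            ext = external_name(inp)
            if ext in network.variables or ext in keep:
                raise ValueError(
                    f"external name {ext!r} collides with an existing variable; "
                    f"rename {ext!r} in the input model"
                )
            renaming[inp] = ext
            if ext not in externals:
                externals.append(ext)
        funcs[v] = f.rename_inputs(renaming)
    return BooleanNetwork(ordered, funcs, externals)


def decompose(network: BooleanNetwork) -> ModularDecomposition:
    """Decompose an autonomous network into its SCC modules."""
    if not network.is_autonomous:
        raise ValueError("decomposition requires an autonomous network; bind externals first")
    net = network.reduced()
    wd = wiring_diagram(net).to_networkx()
    var_index = {v: i for i, v in enumerate(net.variables)}
    sccs = [tuple(sorted(c, key=var_index.__getitem__)) for c in nx.strongly_connected_components(wd)]

    # topological order of the condensation; ties broken by the smallest
    # original variable index so module numbering is reproducible
    scc_of = {v: k for k, c in enumerate(sccs) for v in c}
    succ: dict[int, set[int]] = {k: set() for k in range(len(sccs))}
    indeg = {k: 0 for k in range(len(sccs))}
    for u, w in wd.edges():
        a, b = scc_of[u], scc_of[w]
        if a != b and b not in succ[a]:
            succ[a].add(b)
            indeg[b] += 1
    heap = [(var_index[sccs[k][0]], k) for k in range(len(sccs)) if indeg[k] == 0]
    heapq.heapify(heap)
    topo: list[int] = []
    while heap:
        _, k = heapq.heappop(heap)
        topo.append(k)
        for b in succ[k]:
            indeg[b] -= 1
            if indeg[b] == 0:
                heapq.heappush(heap, (var_index[sccs[b][0]], b))

    renum = {old: new for new, old in enumerate(topo)}
    variable_sets = [sccs[old] for old in topo]
    modules = [restriction(net, s) for s in variable_sets]
    dag = nx.DiGraph()
    dag.add_nodes_from(range(len(sccs)))
    couplings: dict[tuple[int, int], Coupling] = {}
    for old_a, targets in succ.items():
        for old_b in targets:
            i, j = renum[old_a], renum[old_b]
            dag.add_edge(i, j)
            feeding = {
                u: external_name(u)
                for u in variable_sets[i]
                if external_name(u) in modules[j].externals
            }
            couplings[(i, j)] = Coupling.from_dict(feeding)
    return ModularDecomposition(
        network=net,
        modules=modules,
        variable_sets=variable_sets,
        quotient_dag=dag,
        order=tuple(range(len(sccs))),
        couplings=couplings,
    )


def semidirect_product(
    upper: BooleanNetwork, lower: BooleanNetwork, coupling: Coupling | Mapping[str, str]
) -> BooleanNetwork:
    """Couple two networks: substitute upper variables for the lower
    network's external parameters.  Inverse of decomposition on two-module
    networks; with an empty coupling and an autonomous lower network this is
    the disjoint union."""
    if not isinstance(coupling, Coupling):
        coupling = Coupling.from_dict(coupling)
    cmap = coupling.as_dict()
    clash = set(upper.variables) & set(lower.variables)
    if clash:
        raise ValueError(f"variable names shared by both networks: {sorted(clash)}")
    for src, ext in cmap.items():
        if src not in upper.variables:
            raise ValueError(f"coupling source {src!r} is not an upper variable")
        if ext not in lower.externals:
            raise ValueError(f"coupling target {ext!r} is not a lower external")
    unmapped = [e for e in lower.externals if e not in cmap.values()]
    if unmapped:
        raise ValueError(f"lower external parameter(s) left unmapped: {unmapped}")
    inverse = {ext: src for src, ext in cmap.items()}
    variables = upper.variables + lower.variables
    funcs = dict(upper.functions)
    for v in lower.variables:
        funcs[v] = lower.functions[v].rename_inputs(inverse)
    return BooleanNetwork(variables, funcs, upper.externals)


def reorder_variables(network: BooleanNetwork, order: Sequence[str]) -> BooleanNetwork:
    if set(order) != set(network.variables) or len(order) != network.n:
        raise ValueError("order must be a permutation of the network variables")
    return BooleanNetwork(tuple(order), network.functions, network.externals)


def recompose(decomposition: ModularDecomposition) -> BooleanNetwork:
    """Fold the modules back together along the topological order; the result
    is truth-table identical to the decomposed network."""
    current = decomposition.modules[0]
    for j in range(1, decomposition.n_modules):
        module = decomposition.modules[j]
        cmap: dict[str, str] = {}
        for i in range(j):
            c = decomposition.couplings.get((i, j))
            if c:
                cmap.update(c.as_dict())
        current = semidirect_product(current, module, Coupling.from_dict(cmap))
    return reorder_variables(current, decomposition.network.variables)


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------


def substitute_steady_state(
    module: BooleanNetwork, values: Mapping[str, int]
) -> BooleanNetwork:
    """Replace all external parameters by constants (the drive induced by an
    upstream steady state), yielding an autonomous module."""
    return module.bind(values)


def driven_attractors(
    driven: DrivenModule, cap: int = DEFAULT_ENUMERATION_CAP
) -> list[Attractor]:
    """Attractors of a module under a periodic drive g(t).

    Computed on the product space (drive phase, module state), whose
    functional graph has out-degree one; every cycle projects to a periodic
    orbit of module states, which is reduced to its minimal period.  For a
    period-1 drive this coincides with binding the externals and enumerating.
    """
    module, drive = driven.module, driven.drive
    p, m = len(drive), module.n
    if p * (1 << m) > (1 << cap):
        raise ValueError(
            f"product space of size {p}*2^{m} exceeds the enumeration cap 2^{cap}"
        )
    orbits = _product_cycles(module, drive)
    out: set[Attractor] = set()
    for cycle in orbits:
        ys = [y for _, y in cycle]
        out.add(Attractor(minimal_period(ys)))
    return sorted(out, key=lambda a: (a.length, a.states))


def _product_cycles(
    module: BooleanNetwork, drive: Sequence[Mapping[str, int]]
) -> list[list[tuple[int, State]]]:
    """Cycles of the (phase, state) product map, each in successor order."""
    p, m = len(drive), module.n
    bound = [module.bind(g) for g in drive]
    succs = [b._successor_fn() for b in bound]

    def successor(node: tuple[int, int]) -> tuple[int, int]:
        phase, s = node
        return ((phase + 1) % p, succs[phase](s))

    visited: set[tuple[int, int]] = set()
    cycles: list[list[tuple[int, State]]] = []
    for phase0 in range(p):
        for s0 in range(1 << m):
            start = (phase0, s0)
            if start in visited:
                continue
            path: list[tuple[int, int]] = []
            pos: dict[tuple[int, int], int] = {}
            cur = start
            while cur not in visited and cur not in pos:
                pos[cur] = len(path)
                path.append(cur)
                cur = successor(cur)
            if cur in pos:
                cycle = path[pos[cur] :]
                cycles.append(
                    [(ph, _index_to_state(s, m)) for ph, s in cycle]
                )
            visited.update(path)
    return cycles


def drive_from_attractor(
    upper_variables: Sequence[str],
    upper_attractor: Attractor,
    coupling: Coupling | Mapping[str, str],
) -> tuple[dict[str, int], ...]:
    """One period of external bindings induced by an upstream attractor."""
    if not isinstance(coupling, Coupling):
        coupling = Coupling.from_dict(coupling)
    pos = {v: i for i, v in enumerate(upper_variables)}
    drive = []
    for state in upper_attractor.states:
        drive.append({ext: state[pos[src]] for src, ext in coupling.as_dict().items()})
    return tuple(drive)


def compose_attractors(
    upper_variables: Sequence[str],
    upper_attractor: Attractor,
    lower_attractors: Sequence[Attractor],
    lower_module: BooleanNetwork,
    coupling: Coupling | Mapping[str, str],
) -> list[Attractor]:
    """Direct sums C1 (+) C2 over the composed variable list
    ``upper_variables + lower module variables``.

    Each lower attractor is aligned against the upstream drive at every
    cyclic shift; every consistent alignment yields one composed attractor
    (a steady state on either side admits exactly one alignment, while two
    genuine cycles may yield several, one per relative phase).
    """
    if not isinstance(coupling, Coupling):
        coupling = Coupling.from_dict(coupling)
    drive = drive_from_attractor(upper_variables, upper_attractor, coupling)
    p = len(drive)
    out: set[Attractor] = set()
    for lower in lower_attractors:
        r = lower.length
        span = math.lcm(p, r)
        for shift in range(r):
            ok = True
            for t in range(span):
                y = lower.states[(shift + t) % r]
                y_next = lower.states[(shift + t + 1) % r]
                if evaluate(lower_module, y, drive[t % p]) != y_next:
                    ok = False
                    break
            if ok:
                seq = [
                    upper_attractor.states[t % p] + lower.states[(shift + t) % r]
                    for t in range(span)
                ]
                out.add(Attractor(minimal_period(seq)))
    return sorted(out, key=lambda a: (a.length, a.states))


def modular_attractors(
    network: BooleanNetwork, cap: int = DEFAULT_ENUMERATION_CAP
) -> list[Attractor]:
    """Attractors of an autonomous network via its modular decomposition.

    Modules are processed in topological order; each attractor assembled so
    far drives the next module, whose driven attractors are composed on.  The
    result equals whole-network enumeration but never enumerates more than
    (drive period) * 2^(module size) states at a time.
    """
    dec = decompose(network)
    composed_vars: tuple[str, ...] = ()
    current: list[Attractor] = [Attractor(((),))]
    for j in range(dec.n_modules):
        module = dec.modules[j]
        cmap: dict[str, str] = {}
        for i in range(j):
            c = dec.couplings.get((i, j))
            if c:
                cmap.update(c.as_dict())
        coupling = Coupling.from_dict(cmap)
        nxt: set[Attractor] = set()
        for A in current:
            drive = drive_from_attractor(composed_vars, A, coupling)
            lower = driven_attractors(DrivenModule(module, drive), cap=cap)
            nxt.update(
                compose_attractors(composed_vars, A, lower, module, coupling)
            )
        composed_vars = composed_vars + module.variables
        current = list(nxt)
    index = {v: i for i, v in enumerate(composed_vars)}
    perm = [index[v] for v in network.variables]
    result = [
        Attractor(tuple(tuple(s[k] for k in perm) for s in A.states))
        for A in current
    ]
    return sorted(result, key=lambda a: (a.length, a.states))
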