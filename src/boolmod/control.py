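"""Edge and node controls, stabilization checks, and modular control assembly.

An *edge control* pins one input of one target function to a constant:
pinning x_i -> x_j to 0 models deletion of the interaction, pinning to 1 its
constant expression (written x_i ->a x_j when active).  A *node control*
overrides a variable's whole update rule: knock-out (constant 0), constant
expression (constant 1), or — normally disallowed as biologically
impractical — negation of the rule.  In arithmetic over GF(2) the controlled
coordinate functions are

    edge:  f_j(x_1, ..., (mu+1) x_i + mu a, ..., x_n)
    node:  (mu- + mu+ + 1) f_j(x) + mu+

A control set *stabilizes* a network at an attractor C when the controlled
network has C as its only attractor.  Controls found module by module are
assembled into a global control: the union of module controls stabilizes the
full network at the direct sum of the module targets, provided at each
coupling step one side is a steady state (or, failing that, the driven module
has a unique periodic orbit).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .decomposition import (
    Coupling,
    DrivenModule,
    ModularDecomposition,
    compose_attractors,
    drive_from_attractor,
    driven_attractors,
    external_source,
    EXTERNAL_PREFIX,
)
from .network import (
    DEFAULT_ENUMERATION_CAP,
    Attractor,
    BooleanFunction,
    BooleanNetwork,
    attractors,
    wiring_diagram,
)


@dataclass(frozen=True, order=True)
class EdgeControl:
    """Pin the input ``source`` of ``target``'s function to ``value``."""

    source: str
    target: str
    value: int

    def __str__(self) -> str:
        return f"{self.source}->{self.value} {self.target}"


@dataclass(frozen=True, order=True)
class NodeControl:
    """Override ``target``'s update rule: (mu_minus, mu_plus) = (1,0) is
    knock-out, (0,1) constant expression, (1,1) negation (usually rejected),
    (0,0) inactive."""

    target: str
    mu_minus: int
    mu_plus: int

    def __str__(self) -> str:
        kind = {
            (1, 0): "knock-out",
            (0, 1): "constant expression",
            (1, 1): "negation",
            (0, 0): "inactive",
        }[(self.mu_minus, self.mu_plus)]
        return f"{self.target}:={kind}"


@dataclass(frozen=True)
class ControlSet:
    """A set of edge and node controls; the empty set is the identity."""

    edge_controls: frozenset[EdgeControl]
    node_controls: frozenset[NodeControl]

    @classmethod
    def of(cls, *controls: EdgeControl | NodeControl) -> "ControlSet":
        edges = frozenset(c for c in controls if isinstance(c, EdgeControl))
        nodes = frozenset(c for c in controls if isinstance(c, NodeControl))
        cs = cls(edges, nodes)
        cs.validate()
        return cs

    def validate(self) -> None:
        edge_keys = [(c.source, c.target) for c in self.edge_controls]
        if len(set(edge_keys)) != len(edge_keys):
            raise ValueError("at most one edge control per ordered edge")
        node_keys = [c.target for c in self.node_controls]
        if len(set(node_keys)) != len(node_keys):
            raise ValueError("at most one node control per variable")

    def __len__(self) -> int:
        return len(self.edge_controls) + len(self.node_controls)

    def union(self, other: "ControlSet") -> "ControlSet":
        cs = ControlSet(
            self.edge_controls | other.edge_controls,
            self.node_controls | other.node_controls,
        )
        cs.validate()
        return cs

    def sorted_controls(self) -> list[EdgeControl | NodeControl]:
        return sorted(self.node_controls) + sorted(self.edge_controls)

    def __str__(self) -> str:
        if not len(self):
            return "{}"
        return "{" + ", ".join(str(c) for c in self.sorted_controls()) + "}"

    __repr__ = __str__


def apply_edge_control(
    f: BooleanFunction, source: str, value: int, active: bool = True
) -> BooleanFunction:
    """Controlled function for the edge ``source -> target``: inactive
    controls leave f unchanged; an active control substitutes the constant
    ``value`` for ``source`` inside f only (the input stays listed, now
    non-essential)."""
    if source not in f.inputs:
        raise ValueError(f"{source!r} is not an input of the controlled function")
    if not active:
        return f
    return f.pin(source, value)


def apply_node_control(
    f: BooleanFunction, mu_minus: int, mu_plus: int, allow_negation: bool = False
) -> BooleanFunction:
    """Controlled function (mu- + mu+ + 1) f + mu+ over GF(2)."""
    if (mu_minus, mu_plus) == (0, 0):
        return f
    if (mu_minus, mu_plus) == (1, 0):
        return BooleanFunction(f.inputs, (0,) * len(f.table))
    if (mu_minus, mu_plus) == (0, 1):
        return BooleanFunction(f.inputs, (1,) * len(f.table))
    if not allow_negation:
        raise ValueError(
            "(mu-, mu+) = (1, 1) negates the update rule, which is rejected "
            "as biologically impractical; pass allow_negation=True to permit it"
        )
    return f.negate()


def controlled_network(
    network: BooleanNetwork,
    control_set: ControlSet,
    allow_negation: bool = False,
) -> BooleanNetwork:
    """Apply a control set: edge controls first, then node controls, per
    target function.  (Node controls dominate regardless of order.)"""
    control_set.validate()
    funcs = dict(network.functions)
    for ec in sorted(control_set.edge_controls):
        if ec.target not in funcs:
            raise ValueError(f"edge control targets unknown variable {ec.target!r}")
        funcs[ec.target] = apply_edge_control(funcs[ec.target], ec.source, ec.value)
    for nc in sorted(control_set.node_controls):
        if nc.target not in funcs:
            raise ValueError(f"node control targets unknown variable {nc.target!r}")
        funcs[nc.target] = apply_node_control(
            funcs[nc.target], nc.mu_minus, nc.mu_plus, allow_negation=allow_negation
        )
    return BooleanNetwork(network.variables, funcs, network.externals)


def stabilizes(
    network: BooleanNetwork,
    control_set: ControlSet,
    target: Attractor,
    bindings: Mapping[str, int] | None = None,
    cap: int = DEFAULT_ENUMERATION_CAP,
    allow_negation: bool = False,
) -> bool:
    """True iff the controlled network has ``target`` as its only attractor.
    ``target`` may be a new attractor created by the control; it is checked
    against the controlled network only."""
    net = controlled_network(network, control_set, allow_negation=allow_negation)
    found = attractors(net, bindings=bindings, cap=cap)
    return found == [target]


# ---------------------------------------------------------------------------
# Modular assembly
# ---------------------------------------------------------------------------


class AssemblyError(ValueError):
    """A modular control assembly whose side conditions fail, or whose
    assembled claim does not verify."""


def _lift_control(control: EdgeControl | NodeControl, module: BooleanNetwork):
    """Rewrite a module-level control in full-network variable names: an edge
    control whose source is a module external maps back to the upstream
    variable it stands for."""
    if isinstance(control, EdgeControl) and control.source in module.externals:
        return EdgeControl(external_source(control.source), control.target, control.value)
    return control


def assemble_modular_control(
    decomposition: ModularDecomposition,
    module_controls: Sequence[ControlSet],
    module_targets: Sequence[Attractor],
    cap: int = DEFAULT_ENUMERATION_CAP,
    verify: bool = True,
) -> tuple[ControlSet, Attractor]:
    """Assemble per-module controls into a global control and target.

    ``module_controls[k]`` must stabilize module k when driven by the
    composed upstream target; ``module_targets[k]`` is the module-k attractor
    (states in module variable order).  At each coupling step either the
    composed upstream target or the module target must be a steady state;
    otherwise the driven module must still have a unique periodic orbit, and
    an :class:`AssemblyError` is raised when neither holds.  The assembled
    claim is re-verified by whole-network enumeration whenever the network
    fits the cap; a discrepancy raises rather than passing silently.
    """
    m = decomposition.n_modules
    if len(module_controls) != m or len(module_targets) != m:
        raise ValueError(f"need exactly {m} module controls and targets")

    full_controls = ControlSet(frozenset(), frozenset())
    composed_vars: tuple[str, ...] = ()
    composed = Attractor(((),))
    for j in range(m):
        module = decomposition.modules[j]
        ctrl = module_controls[j]
        target = module_targets[j]
        ctrl_module = controlled_network(module, ctrl)
        cmap: dict[str, str] = {}
        for i in range(j):
            c = decomposition.couplings.get((i, j))
            if c:
                cmap.update(c.as_dict())
        coupling = Coupling.from_dict(cmap)
        drive = drive_from_attractor(composed_vars, composed, coupling)
        found = driven_attractors(DrivenModule(ctrl_module, drive), cap=cap)
        if found != [target]:
            raise AssemblyError(
                f"control {ctrl} does not stabilize module {j} at {target} under "
                f"the upstream drive; driven attractors are {found}"
            )
        if not (composed.is_steady_state or target.is_steady_state):
            # the direct-sum argument needs a steady state on one side; fall
            # back to checking uniqueness of the driven periodic orbit
            composed_candidates = compose_attractors(
                composed_vars, composed, found, ctrl_module, coupling
            )
            if len(composed_candidates) != 1:
                raise AssemblyError(
                    f"at module {j} neither the composed upstream target "
                    f"{composed} nor the module target {target} is a steady "
                    f"state, and the driven orbit is not unique; the direct "
                    f"sum is ambiguous"
                )
            composed = composed_candidates[0]
        else:
            (composed,) = compose_attractors(
                composed_vars, composed, [target], ctrl_module, coupling
            )
        composed_vars = composed_vars + module.variables
        lifted = ControlSet.of(
            *(_lift_control(c, module) for c in ctrl.sorted_controls())
        )
        full_controls = full_controls.union(lifted)

    index = {v: i for i, v in enumerate(composed_vars)}
    perm = [index[v] for v in decomposition.network.variables]
    global_target = Attractor(
        tuple(tuple(s[k] for k in perm) for s in composed.states)
    )
    if verify and decomposition.network.n <= cap:
        if not stabilizes(decomposition.network, full_controls, global_target, cap=cap):
            raise AssemblyError(
                f"assembled control {full_controls} fails the whole-network "
                f"stabilization check at {global_target}"
            )
    return full_controls, global_target


# ---------------------------------------------------------------------------
# Exhaustive module-level control search
# ---------------------------------------------------------------------------


def _candidate_controls(
    module: BooleanNetwork,
    kinds: str,
    allow_negation: bool,
) -> list[EdgeControl | NodeControl]:
    """Atomic candidates in deterministic search order: node controls first
    (by variable index, knock-out before constant expression), then edge
    controls (lexicographic by source, target, pinned value)."""
    idx = {v: i for i, v in enumerate(module.variables)}
    cands: list[EdgeControl | NodeControl] = []
    if kinds in ("node", "both"):
        for v in module.variables:
            cands.append(NodeControl(v, 1, 0))
            cands.append(NodeControl(v, 0, 1))
            if allow_negation:
                cands.append(NodeControl(v, 1, 1))
    if kinds in ("edge", "both"):
        wd = wiring_diagram(module)
        edges = sorted(wd.edges, key=lambda e: (idx[e[0]], idx[e[1]]))
        for src, tgt in edges:
            for a in (0, 1):
                cands.append(EdgeControl(src, tgt, a))
    return cands


def search_module_control(
    module: BooleanNetwork,
    target: Attractor,
    max_size: int = 2,
    kinds: str = "both",
    bindings: Mapping[str, int] | None = None,
    allow_negation: bool = False,
    cap: int = DEFAULT_ENUMERATION_CAP,
) -> list[ControlSet]:
    """All control sets of minimal cardinality (<= max_size) stabilizing the
    module at ``target``, by breadth-first search over cardinality.

    ``target`` may be an attractor the control itself creates.  The returned
    family is superset-free (all members share the minimal cardinality) and
    deterministically ordered.  An empty list means nothing of size
    <= max_size works.
    """
    if kinds not in ("node", "edge", "both"):
        raise ValueError(f"kinds must be 'node', 'edge' or 'both', got {kinds!r}")
    net = module.bind(bindings) if module.externals or bindings else module
    cands = _candidate_controls(net, kinds, allow_negation)
    for size in range(0, max_size + 1):
        hits: list[ControlSet] = []
        for combo in itertools.combinations(cands, size):
            try:
                cs = ControlSet.of(*combo)
            except ValueError:
                continue  # conflicting controls on one node or edge
            if stabilizes(net, cs, target, cap=cap, allow_negation=allow_negation):
                hits.append(cs)
        if hits:
            return hits
    return []
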