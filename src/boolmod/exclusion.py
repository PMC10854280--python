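"""Phenotypes and exclusion of modules from the control search.

A *phenotype* is defined by marker variables with required values; all
attractors agreeing on the markers share the phenotype.  When the goal is to
stabilize a phenotype rather than a full attractor, whole modules can often
be dropped from the control search:

* a module with no directed path to any marker-holding module cannot affect
  the phenotype at all (reachability exclusion), and
* an upstream module whose only influence enters a downstream module through
  bridging nodes with canalizing update rules can be *decoupled*: fixing a
  variable that sits in a more dominant canalizing layer than every upstream
  regulator (node-control route), or pinning an upstream regulator that sits
  in the most dominant layer to its canalizing input (edge-control route),
  makes the bridging functions independent of the upstream module.

Every proposed decoupling control is verified on the truth table: after
applying it, the bridging function must be non-essential in all upstream
regulators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .canalization import CanalizingLayers, layer_decomposition
from .control import EdgeControl, NodeControl
from .decomposition import ModularDecomposition
from .network import Attractor, BooleanFunction, BooleanNetwork


@dataclass(frozen=True)
class Phenotype:
    """Marker variables with their required values."""

    markers: tuple[tuple[str, int], ...]

    @classmethod
    def from_dict(cls, d: Mapping[str, int]) -> "Phenotype":
        if not d:
            raise ValueError("a phenotype needs at least one marker")
        return cls(tuple(sorted((k, int(v)) for k, v in d.items())))

    def as_dict(self) -> dict[str, int]:
        return dict(self.markers)

    def marker_names(self) -> tuple[str, ...]:
        return tuple(k for k, _ in self.markers)


def phenotype_of(attractor: Attractor, phenotype: Phenotype, variables: Sequence[str]) -> bool:
    """True iff every state of the attractor shows the required marker
    values.  A marker oscillating across the attractor never matches."""
    if not phenotype.markers:
        raise ValueError("a phenotype needs at least one marker")
    pos = {v: i for i, v in enumerate(variables)}
    for name, value in phenotype.markers:
        if name not in pos:
            raise KeyError(f"marker {name!r} is not a network variable")
        if any(state[pos[name]] != value for state in attractor.states):
            return False
    return True


def chain_condition(
    quotient_dag: nx.DiGraph,
    i: int,
    j: int,
    phenotype_modules: Sequence[int],
) -> bool:
    """True iff every directed path in the quotient DAG from module i to a
    marker-holding module passes through module j (markers in i itself fail;
    marker modules unreachable from i are vacuously fine)."""
    if i == j:
        raise ValueError("i and j must be distinct modules")
    pruned = quotient_dag.copy()
    pruned.remove_node(j)
    for k in set(phenotype_modules):
        if k == j:
            continue
        if k == i:
            return False
        if pruned.has_node(k) and nx.has_path(pruned, i, k):
            return False
    return True


@dataclass(frozen=True)
class BridgingNode:
    """One downstream node regulated from an upstream module."""

    name: str
    decomposition_of_rule: CanalizingLayers
    upstream_regulators: tuple[str, ...]
    dominant_upstream_layer: int  # ell; r+1 when upstream inputs are core-only


def bridging_analysis(
    decomposition: ModularDecomposition, i: int, j: int
) -> list[BridgingNode]:
    """Layer-analyze every node of module j whose update rule reads module-i
    variables.  ``dominant_upstream_layer`` is the most dominant (smallest)
    layer index holding an upstream regulator, or r+1 if they all sit in the
    core polynomial."""
    if not decomposition.quotient_dag.has_edge(i, j):
        raise ValueError(f"no quotient-DAG edge {i} -> {j}")
    upstream = set(decomposition.variable_sets[i])
    reports = []
    for x in decomposition.variable_sets[j]:
        fx = decomposition.network.functions[x].reduced()
        regs = tuple(v for v in fx.inputs if v in upstream)
        if not regs:
            continue
        layers = layer_decomposition(fx)
        ell = min(layers.layer_of(v) for v in regs)
        reports.append(
            BridgingNode(
                name=x,
                decomposition_of_rule=layers,
                upstream_regulators=regs,
                dominant_upstream_layer=ell,
            )
        )
    return reports


@dataclass(frozen=True)
class DecouplingProposal:
    """A verified control that severs one bridging node from the upstream
    module.  ``route`` is "edge" (pin a most-dominant-layer upstream
    regulator to its canalizing input) or "node" (fix a more dominant
    non-upstream variable to its canalizing input)."""

    bridging_node: str
    control: EdgeControl | NodeControl
    route: str
    controlled_variable: str
    canalizing_input: int


def _decouples(fx: BooleanFunction, pinned: Mapping[str, int], regs: Sequence[str]) -> bool:
    """Does pinning ``pinned`` make fx non-essential in every regulator?"""
    g = fx
    for v, a in pinned.items():
        g = g.pin(v, a)
    return all(not g.is_essential_in(v) for v in regs if v in g.inputs)


def decoupling_controls(
    decomposition: ModularDecomposition, i: int, j: int
) -> dict[str, list[DecouplingProposal]]:
    """Verified decoupling proposals per bridging node of the edge i -> j.

    Edge-control proposals (on most-dominant-layer upstream inputs) are
    listed before node-control proposals on dominant non-upstream variables.
    A bridging node whose upstream inputs all sit in the core polynomial,
    with no more dominant canalizing variable elsewhere, gets an empty list.
    """
    upstream = set(decomposition.variable_sets[i])
    out: dict[str, list[DecouplingProposal]] = {}
    for node in bridging_analysis(decomposition, i, j):
        fx = decomposition.network.functions[node.name].reduced()
        layers = node.decomposition_of_rule
        ell = node.dominant_upstream_layer
        proposals: list[DecouplingProposal] = []
        # edge route: an upstream regulator in the most dominant layer
        if layers.n_layers >= 1 and ell == 1:
            for v, a in layers.layers[0]:
                if v in upstream and _decouples(fx, {v: a}, node.upstream_regulators):
                    proposals.append(
                        DecouplingProposal(
                            bridging_node=node.name,
                            control=EdgeControl(v, node.name, a),
                            route="edge",
                            controlled_variable=v,
                            canalizing_input=a,
                        )
                    )
        # node route: a non-upstream variable strictly more dominant than ell
        for li in range(min(ell - 1, layers.n_layers)):
            for v, a in layers.layers[li]:
                if v in upstream:
                    continue
                if _decouples(fx, {v: a}, node.upstream_regulators):
                    mu = (1, 0) if a == 0 else (0, 1)
                    proposals.append(
                        DecouplingProposal(
                            bridging_node=node.name,
                            control=NodeControl(v, *mu),
                            route="node",
                            controlled_variable=v,
                            canalizing_input=a,
                        )
                    )
        out[node.name] = proposals
    return out


@dataclass(frozen=True)
class ExclusionReport:
    """Why (and how) one module can be dropped from the control search."""

    module: int
    reason: str  # "unreachable" or "decoupling"
    via_module: int | None = None
    bridging: tuple[BridgingNode, ...] = ()
    proposals: tuple[DecouplingProposal, ...] = ()


def excludable_modules(
    decomposition: ModularDecomposition, phenotype: Phenotype
) -> list[ExclusionReport]:
    """All modules excludable from the phenotype-control search.

    A module is excluded (a) when no directed path links it to any
    marker-holding module, or (b) when all of its influence enters a single
    successor module j satisfying the chain condition, and every bridging
    node there admits a verified decoupling control.
    """
    dag = decomposition.quotient_dag
    marker_modules = sorted(
        {decomposition.module_of(name) for name in phenotype.marker_names()}
    )
    reports: list[ExclusionReport] = []
    for i in range(decomposition.n_modules):
        if i in marker_modules:
            continue
        reachable = {
            k for k in marker_modules if nx.has_path(dag, i, k)
        }
        if not reachable:
            reports.append(ExclusionReport(module=i, reason="unreachable"))
            continue
        for j in dag.successors(i):
            if j == i:
                continue
            if not chain_condition(dag, i, j, marker_modules):
                continue
            # all other influence of i must be unable to reach the markers,
            # so that cutting the direct i -> j bridges severs i completely
            others_safe = all(
                not any(nx.has_path(dag, s, k) for k in marker_modules)
                for s in dag.successors(i)
                if s != j
            )
            if not others_safe:
                continue
            per_node = decoupling_controls(decomposition, i, j)
            if per_node and all(props for props in per_node.values()):
                bridging = tuple(bridging_analysis(decomposition, i, j))
                proposals = tuple(
                    p for props in per_node.values() for p in props
                )
                reports.append(
                    ExclusionReport(
                        module=i,
                        reason="decoupling",
                        via_module=j,
                        bridging=bridging,
                        proposals=proposals,
                    )
                )
                break
    return reports
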