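"""Seeded random Boolean networks with a prescribed modular structure.

The generator builds networks whose wiring diagram has exactly the requested
strongly connected modules and quotient DAG: each module of size k >= 2 gets
an internal directed cycle (guaranteeing strong connectivity) plus optional
random chords, and every requested DAG edge places at least one cross-module
input.  Update rules are drawn either from the nested canalizing family —
the family that dominates published biological models — or uniformly at
random over the chosen inputs; in both cases every designed input is
essential, so the decomposition of the result recovers the design exactly.

All draws come from a single numpy Generator, so output is bit-reproducible
per seed.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .canalization import random_ncf
from .network import BooleanFunction, BooleanNetwork

FAMILIES = ("ncf", "random")


def random_function(
    inputs: Sequence[str],
    rng: np.random.Generator,
    family: str = "ncf",
) -> BooleanFunction:
    """A random update rule, essential in every listed input."""
    inputs = tuple(inputs)
    if family == "ncf":
        if not inputs:
            return BooleanFunction.constant(int(rng.integers(2)))
        return random_ncf(len(inputs), seed=rng, variables=inputs)
    if family != "random":
        raise ValueError(f"unknown function family {family!r}; use one of {FAMILIES}")
    if not inputs:
        return BooleanFunction.constant(int(rng.integers(2)))
    m = len(inputs)
    while True:  # resample until all inputs are essential
        table = rng.integers(0, 2, size=1 << m)
        f = BooleanFunction(inputs, table.tolist())
        if all(f.is_essential_in(v) for v in inputs):
            return f


def _check_dag(n_modules: int, dag_edges: Sequence[tuple[int, int]]) -> None:
    order = {}
    for i, j in dag_edges:
        if not (0 <= i < n_modules and 0 <= j < n_modules):
            raise ValueError(f"edge ({i}, {j}) references an unknown module")
        if i >= j:
            raise ValueError(
                f"edge ({i}, {j}) is not forward in module order; module "
                f"DAG edges must satisfy i < j (acyclicity)"
            )
    del order


def generate_modular_network(
    module_sizes: Sequence[int],
    dag_edges: Sequence[tuple[int, int]] = (),
    family: str = "ncf",
    seed: int | np.random.Generator | None = None,
    chord_probability: float = 0.25,
    max_in_degree: int = 5,
) -> BooleanNetwork:
    """Generate a random network with the given module sizes and quotient DAG.

    Modules are numbered 0..m-1 and their variables named ``x1..xN`` in
    module order; DAG edges must run forward in that numbering (i < j).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sizes = [int(s) for s in module_sizes]
    if not sizes or any(s < 1 for s in sizes):
        raise ValueError("module sizes must be positive")
    _check_dag(len(sizes), list(dag_edges))

    # variable names, module by module
    names: list[list[str]] = []
    count = 0
    for s in sizes:
        names.append([f"x{count + k + 1}" for k in range(s)])
        count += s

    inputs: dict[str, list[str]] = {v: [] for mod in names for v in mod}
    # internal cycle plus random chords keeps each module strongly connected
    for mod in names:
        k = len(mod)
        if k >= 2:
            for t in range(k):
                inputs[mod[(t + 1) % k]].append(mod[t])
            for src in mod:
                for tgt in mod:
                    if src == tgt or src in inputs[tgt]:
                        continue
                    if len(inputs[tgt]) < max_in_degree and rng.random() < chord_probability:
                        inputs[tgt].append(src)
        elif rng.random() < chord_probability:
            inputs[mod[0]].append(mod[0])  # occasional self-loop on a trivial module

    # at least one cross-module input per requested DAG edge
    for i, j in dag_edges:
        n_cross = 1 + int(rng.integers(0, 2))
        for _ in range(n_cross):
            src = names[i][int(rng.integers(len(names[i])))]
            candidates = [
                t for t in names[j] if src not in inputs[t] and len(inputs[t]) < max_in_degree
            ]
            if not candidates:
                candidates = [t for t in names[j] if src not in inputs[t]]
            if candidates:
                tgt = candidates[int(rng.integers(len(candidates)))]
                inputs[tgt].append(src)

    variables = [v for mod in names for v in mod]
    functions = {
        v: random_function(inputs[v], rng, family=family) for v in variables
    }
    return BooleanNetwork(variables, functions)
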