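"""Shared fixtures: worked-example networks and an independent attractor oracle."""

from __future__ import annotations

import numpy as np
import pytest

import boolmod as bm


@pytest.fixture
def net_3node() -> bm.BooleanNetwork:
    """F(x1,x2,x3) = (x2 & !x3, x3, !x1 & x2): two steady states, one 2-cycle."""
    return bm.load_fixture("three_node_multistable")


@pytest.fixture
def net_decomposable() -> bm.BooleanNetwork:
    """4-node network with modules {x1,x2} and {x3,x4}."""
    return bm.load_fixture("two_module_feedforward")


@pytest.fixture
def net_coupled() -> bm.BooleanNetwork:
    """F(x1,x2,x3,x4) = (x2, x1, x2 & x4, x3), the modular-control example."""
    return bm.load_fixture("two_module_relay")


def attractor(*bit_strings: str) -> bm.Attractor:
    return bm.Attractor(tuple(bm.parse_state(s) for s in bit_strings))


def brute_force_attractors(net: bm.BooleanNetwork) -> set[bm.Attractor]:
    """Independent oracle: iterate F from every state until a state repeats,
    then read off the cycle.  Uses only the one-step evaluator."""
    found: set[bm.Attractor] = set()
    for idx in range(1 << net.n):
        x = tuple((idx >> (net.n - 1 - i)) & 1 for i in range(net.n))
        seen: dict[tuple, int] = {}
        seq = []
        while x not in seen:
            seen[x] = len(seq)
            seq.append(x)
            x = bm.evaluate(net, x)
        found.add(bm.Attractor(tuple(seq[seen[x]:])))
    return found


def random_network(
    rng: np.random.Generator, n: int, max_in: int = 3
) -> bm.BooleanNetwork:
    """A uniform random network: each variable reads 1..max_in random
    variables through a random truth table."""
    names = [f"x{i+1}" for i in range(n)]
    funcs = {}
    for v in names:
        k = int(rng.integers(1, min(max_in, n) + 1))
        ins = [names[i] for i in rng.choice(n, size=k, replace=False)]
        table = [int(b) for b in rng.integers(0, 2, size=1 << k)]
        funcs[v] = bm.BooleanFunction(ins, table)
    return bm.BooleanNetwork(names, funcs)
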