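"""Bundled worked-example networks.

Small networks used throughout the documentation and test-suite: a 3-node
network with two steady states and a 2-cycle, a 4-node decomposable network
with two strongly connected modules, the 4-node coupled network used for the
modular-control examples, two nested canalizing rules with layer structures
(1,1,2) and (1,3), and the DISC rule of the T-LGL leukemia model (the death
inducing signaling complex activated by ceramide or by Fas in the absence of
FLIP).

The full 16-node T-LGL network is not bundled: only its wiring diagram and
the DISC rule are public in the source describing this analysis; the
complete rule set must be supplied by the user as a rule file.
"""

from __future__ import annotations

import os

from .network import BooleanNetwork
from .parse import parse_rules, read_network

_FIXTURE_RULES: dict[str, str] = {
    # 3-node network: F = (x2 & !x3, x3, !x1 & x2)
    "three_node_multistable": """\
x1, x2 & !x3
x2, x3
x3, !x1 & x2
""",
    # 4-node decomposable network with modules {x1,x2} and {x3,x4}
    "two_module_feedforward": """\
x1, x2 & x1
x2, !x1
x3, x1 | !x4
x4, (x1 & !x2) | (x3 & x4)
""",
    # 4-node coupled network used in the modular-control examples
    "two_module_relay": """\
x1, x2
x2, x1
x3, x2 & x4
x4, x3
""",
    # nested canalizing rule with layer structure (1, 1, 2)
    "ncf_layers_112": """\
f, x1 & (!x2 | (x3 & x4))
""",
    # nested canalizing rule with layer structure (1, 3)
    "ncf_layers_13": """\
g, x1 & (!x2 | x3 | x4)
""",
    # DISC rule of the T-LGL model; Ceramide, Fas and FLIP are externals
    "fDISC": """\
DISC, Ceramide | (Fas & !FLIP)
""",
}


def fixture_names() -> list[str]:
    return sorted(_FIXTURE_RULES)


def load_fixture(name: str) -> BooleanNetwork:
    """Parse one bundled network by name."""
    if name not in _FIXTURE_RULES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_names())}"
        )
    return parse_rules(_FIXTURE_RULES[name])


def fixtures() -> dict[str, BooleanNetwork]:
    """All bundled networks, freshly parsed."""
    return {name: load_fixture(name) for name in fixture_names()}


def fixture_rules(name: str) -> str:
    """The raw rule text of a bundled network."""
    if name not in _FIXTURE_RULES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_names())}"
        )
    return _FIXTURE_RULES[name]


def load_tlgl(path: str | os.PathLike | None = None) -> BooleanNetwork:
    """Load a user-supplied T-LGL leukemia model rule file.

    The 16-node rule set is not redistributed with this package; export it
    from its original publication as a ``target, factors`` rule file and pass
    the path here.
    """
    if path is None or not os.path.exists(path):
        raise FileNotFoundError(
            "the T-LGL model rules are not bundled: only the wiring diagram "
            "and the DISC rule are public in the analysis this package "
            "implements.  Obtain the 16-node rule set from the original "
            "T-LGL publication, save it as a 'target, factors' rule file, "
            "and pass its path to load_tlgl()."
        )
    net = read_network(path)
    if net.n != 16:
        raise ValueError(
            f"expected the 16-node T-LGL model, got {net.n} variables"
        )
    return net
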