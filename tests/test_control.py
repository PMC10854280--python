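"""Edge/node control operators, stabilization, assembly, and search."""

import numpy as np
import pytest

import boolmod as bm
from boolmod.control import AssemblyError, ControlSet, EdgeControl, NodeControl

from conftest import attractor, random_network


class TestEdgeControl:
    def test_constant_expression_of_edge(self, net_coupled):
        f2 = net_coupled.functions["x2"]  # x2' = x1
        pinned = bm.apply_edge_control(f2, "x1", 1)
        assert pinned.reduced().is_constant and pinned.reduced().table[0] == 1

    def test_edge_deletion(self, net_coupled):
        f1 = net_coupled.functions["x1"]  # x1' = x2
        pinned = bm.apply_edge_control(f1, "x2", 0)
        assert pinned.reduced().is_constant and pinned.reduced().table[0] == 0

    def test_inactive_control_is_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            f = bm.random_function(["a", "b", "c"], rng, family="random")
            assert bm.apply_edge_control(f, "b", 1, active=False) == f

    def test_active_control_makes_source_non_essential(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            f = bm.random_function(["a", "b", "c"], rng, family="random")
            for a in (0, 1):
                assert not bm.apply_edge_control(f, "a", a).is_essential_in("a")

    def test_source_must_be_an_input(self, net_coupled):
        with pytest.raises(ValueError, match="x3"):
            bm.apply_edge_control(net_coupled.functions["x1"], "x3", 1)


class TestNodeControl:
    def test_contract_table_on_random_functions(self):
        """(0,0) identity, (1,0) knock-out, (0,1) constant expression,
        (1,1) rule negation, for 100 random functions."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            k = int(rng.integers(1, 4))
            f = bm.random_function([f"v{i}" for i in range(k)], rng, family="random")
            assert bm.apply_node_control(f, 0, 0) == f
            assert set(bm.apply_node_control(f, 1, 0).table) == {0}
            assert set(bm.apply_node_control(f, 0, 1).table) == {1}
            neg = bm.apply_node_control(f, 1, 1, allow_negation=True)
            assert all(a != b for a, b in zip(neg.table, f.table))

    def test_negation_rejected_by_default(self):
        f = bm.parse_expression("a")
        with pytest.raises(ValueError, match="negat"):
            bm.apply_node_control(f, 1, 1)


class TestControlledNetwork:
    def test_two_edge_controls_force_unique_attractor(self, net_coupled):
        cs = ControlSet.of(EdgeControl("x1", "x2", 1), EdgeControl("x4", "x3", 1))
        net = bm.controlled_network(net_coupled, cs)
        assert bm.attractors(net) == [attractor("1111")]

    def test_empty_control_set_is_identity(self, net_coupled):
        cs = ControlSet.of()
        net = bm.controlled_network(net_coupled, cs)
        assert net.equivalent_to(net_coupled)

    def test_knock_out_of_every_node_gives_zero_state(self, net_3node):
        cs = ControlSet.of(*(NodeControl(v, 1, 0) for v in net_3node.variables))
        assert bm.attractors(bm.controlled_network(net_3node, cs)) == [attractor("000")]

    def test_conflicting_controls_rejected(self):
        with pytest.raises(ValueError, match="one edge control"):
            ControlSet.of(EdgeControl("a", "b", 0), EdgeControl("a", "b", 1))
        with pytest.raises(ValueError, match="one node control"):
            ControlSet.of(NodeControl("a", 1, 0), NodeControl("a", 0, 1))


class TestStabilizes:
    def test_four_edge_controls_stabilize_at_new_attractor(self, net_coupled):
        cs = ControlSet.of(
            EdgeControl("x1", "x2", 1), EdgeControl("x2", "x1", 0),
            EdgeControl("x4", "x3", 1), EdgeControl("x3", "x4", 0),
        )
        assert bm.stabilizes(net_coupled, cs, attractor("0110"))

    def test_uncontrolled_multistable_network_is_not_stabilized(self, net_3node):
        assert not bm.stabilizes(net_3node, ControlSet.of(), attractor("000"))

    def test_non_attractor_target_fails(self, net_coupled):
        cs = ControlSet.of(EdgeControl("x1", "x2", 1))
        assert not bm.stabilizes(net_coupled, cs, attractor("0000"))


class TestAssembly:
    def test_new_target_attractor(self, net_coupled):
        dec = bm.decompose(net_coupled)
        mu1 = ControlSet.of(EdgeControl("x1", "x2", 1), EdgeControl("x2", "x1", 0))
        mu2 = ControlSet.of(EdgeControl("x4", "x3", 1), EdgeControl("x3", "x4", 0))
        full, target = bm.assemble_modular_control(
            dec, [mu1, mu2], [attractor("01"), attractor("10")]
        )
        assert target == attractor("0110")
        assert len(full) == 4
        assert bm.stabilizes(net_coupled, full, target)

    def test_existing_target_attractor(self, net_coupled):
        dec = bm.decompose(net_coupled)
        full, target = bm.assemble_modular_control(
            dec,
            [ControlSet.of(EdgeControl("x1", "x2", 1)),
             ControlSet.of(EdgeControl("x4", "x3", 1))],
            [attractor("11"), attractor("11")],
        )
        assert target == attractor("1111")
        assert full == ControlSet.of(
            EdgeControl("x1", "x2", 1), EdgeControl("x4", "x3", 1)
        )

    def test_single_module_passthrough(self, net_3node):
        dec = bm.decompose(net_3node)
        mu = ControlSet.of(*(NodeControl(v, 1, 0) for v in net_3node.variables))
        full, target = bm.assemble_modular_control(dec, [mu], [attractor("000")])
        assert full == mu and target == attractor("000")

    def test_wrong_module_control_raises(self, net_coupled):
        dec = bm.decompose(net_coupled)
        with pytest.raises(AssemblyError, match="does not stabilize"):
            bm.assemble_modular_control(
                dec, [ControlSet.of(), ControlSet.of()],
                [attractor("11"), attractor("11")],
            )


class TestSearch:
    def test_node_controls_for_steady_state(self, net_coupled):
        f1 = bm.decompose(net_coupled).modules[0]
        hits = bm.search_module_control(f1, attractor("11"), kinds="node")
        assert ControlSet.of(NodeControl("x1", 0, 1)) in hits
        assert ControlSet.of(NodeControl("x2", 0, 1)) in hits
        assert all(len(cs) == 1 for cs in hits)

    def test_edge_controls_for_new_steady_state(self, net_coupled):
        f1 = bm.decompose(net_coupled).modules[0]
        hits = bm.search_module_control(f1, attractor("01"), kinds="edge")
        assert ControlSet.of(
            EdgeControl("x1", "x2", 1), EdgeControl("x2", "x1", 0)
        ) in hits

    def test_empty_control_minimal_for_unique_attractor(self):
        net = bm.parse_rules("a, 1\nb, a\n")
        hits = bm.search_module_control(net, attractor("11"))
        assert hits == [ControlSet.of()]

    def test_no_result_within_budget_is_empty(self, net_coupled):
        hits = bm.search_module_control(
            net_coupled, attractor("0110"), max_size=1, kinds="node"
        )
        assert hits == []

    def test_returned_family_is_superset_free(self, net_coupled):
        hits = bm.search_module_control(net_coupled, attractor("1111"), max_size=2)
        for a in hits:
            for b in hits:
                if a is b:
                    continue
                joint = a.edge_controls <= b.edge_controls and a.node_controls <= b.node_controls
                assert not joint


class TestModularControlTheorem:
    def test_assembled_module_controls_stabilize_full_network(self):
        """Controls found module by module, assembled along the coupling,
        stabilize the full network at the direct-sum target: the modular
        control guarantee as an executable property on 50 random networks."""
        rng = np.random.default_rng(20240)
        for _ in range(50):
            net = bm.generate_modular_network(
                [int(rng.integers(2, 5)), int(rng.integers(2, 5))],
                [(0, 1)], family="ncf", seed=rng,
            )
            dec = bm.decompose(net)
            controls, targets = [], []
            composed_bindings = {}
            for j, mod in enumerate(dec.modules):
                tgt = attractor("1" * mod.n)
                bindings = {e: composed_bindings[e] for e in mod.externals}
                hits = bm.search_module_control(
                    mod, tgt, max_size=2, kinds="both", bindings=bindings
                )
                if hits:
                    cs = hits[0]
                else:
                    # constant expression of every module node always works
                    cs = ControlSet.of(*(NodeControl(v, 0, 1) for v in mod.variables))
                controls.append(cs)
                targets.append(tgt)
                composed_bindings.update(
                    {f"e_{v}": 1 for v in dec.variable_sets[j]}
                )
            full, target = bm.assemble_modular_control(dec, controls, targets)
            assert bm.stabilizes(net, full, target)
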