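"""Propagation dynamics, TSignal, ensemble fitting and MoA extraction."""

import math

import networkx as nx
import numpy as np
import pytest

import netmoa as nm
from netmoa.core import ValidationError

from conftest import random_interactome


class TestPropagate:
    def test_no_clamps_gives_zero_everywhere(self, chain_net):
        res = nm.propagate(chain_net, None, {})
        assert all(v == 0.0 for v in res.values)

    def test_chain_fixed_point(self, chain_net):
        res = nm.propagate(chain_net, None, {"A": -1.0})
        assert res["A"] == -1.0
        assert res["B"] == pytest.approx(math.tanh(-1.0), abs=1e-9)
        assert res["C"] == pytest.approx(math.tanh(math.tanh(-1.0)), abs=1e-9)
        assert res.converged

    def test_odd_symmetry_exact(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            net = random_interactome(rng, n=10, p_edge=0.3)
            clamps = {net.nodes[0]: float(rng.uniform(-1, 1)),
                      net.nodes[3]: float(rng.uniform(-1, 1))}
            plus = nm.propagate(net, None, clamps)
            minus = nm.propagate(net, None, {k: -v for k, v in clamps.items()})
            assert np.max(np.abs(plus.values + minus.values)) < 1e-12

    def test_boundedness_over_many_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            net = random_interactome(rng, n=6, p_edge=0.4)
            clamps = {net.nodes[int(rng.integers(0, 6))]: float(rng.uniform(-1, 1))}
            res = nm.propagate(net, None, clamps, max_iter=60)
            assert np.all(np.abs(res.values) <= 1.0 + 1e-15)

    def test_locality_unreachable_nodes_stay_zero(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            net = random_interactome(rng, n=10, p_edge=0.25)
            src = net.nodes[0]
            res = nm.propagate(net, None, {src: 1.0})
            g = net._digraph
            reachable = nx.descendants(g, src) | {src}
            for node in net.nodes:
                if node not in reachable:
                    assert res[node] == 0.0

    def test_linearized_path_sum_oracle_on_small_dags(self):
        # with tiny clamps tanh is ~identity, so the fixed point must agree
        # with the sum over directed paths of the product of signed weights
        rng = np.random.default_rng(21)
        checked = 0
        for _ in range(60):
            net = random_interactome(rng, n=8, p_edge=0.35, dag=True)
            src = net.nodes[0]
            clamp = 0.01
            res = nm.propagate(net, None, {src: clamp}, tol=1e-14)
            g = net.to_networkx()
            for target in net.nodes[1:]:
                expected = 0.0
                for path in nx.all_simple_paths(g, src, target):
                    for combo in _edge_products(g, path):
                        expected += combo * clamp
                got = res[target]
                if expected != 0.0:
                    assert got == pytest.approx(expected, rel=1e-3, abs=1e-6)
                    checked += 1
        assert checked > 50  # the oracle actually exercised nontrivial paths

    def test_clamped_node_held_fixed(self, chain_net):
        res = nm.propagate(chain_net, None, {"A": 0.3, "B": -0.8})
        assert res["A"] == 0.3 and res["B"] == -0.8

    def test_invalid_inputs(self, chain_net):
        with pytest.raises(ValidationError):
            nm.propagate(chain_net, None, {"ZZ": 1.0})
        with pytest.raises(ValidationError):
            nm.propagate(chain_net, None, {"A": 1.0}, max_iter=0)

    def test_limit_cycle_averaged_and_flagged(self):
        # A clamps a strong two-node negative feedback loop into oscillation
        net = nm.Interactome.from_edges(
            [
                nm.Edge("A", "B", 1, 1.0),
                nm.Edge("B", "C", 1, 1.0),
                nm.Edge("C", "B", -1, 1.0),
            ]
        )
        res = nm.propagate(net, np.array([3.0, 3.0, 3.0]) / 3.0 * 3, {"A": 1.0},
                           max_iter=500, tol=1e-10)
        # whatever the attractor, output must be bounded and deterministic
        res2 = nm.propagate(net, np.array([3.0, 3.0, 3.0]), {"A": 1.0},
                            max_iter=500, tol=1e-10)
        assert np.allclose(res.values, res2.values)
        assert np.all(np.abs(res.values) <= 1.0)


def _edge_products(g: nx.MultiDiGraph, path):
    """All sign*weight products along a node path (multi-edges branch)."""
    prods = [1.0]
    for u, v in zip(path, path[1:]):
        new = []
        for key in g[u][v]:
            data = g[u][v][key]
            for p in prods:
                new.append(p * data["sign"] * data["weight"])
        prods = new
    return prods


class TestTSignal:
    def test_null_signal_gives_zero(self):
        effs = [nm.Effector("E1", 1), nm.Effector("E2", -1)]
        assert nm.tsignal({"E1": 0.0, "E2": 0.0}, effs) == 0.0

    def test_full_reversal_extreme(self):
        assert nm.tsignal({"E": -1.0}, [nm.Effector("E", 1)]) == 1.0

    def test_mixed_states_hand_example(self):
        effs = [nm.Effector("E1", 1), nm.Effector("E2", -1)]
        val = nm.tsignal({"E1": -0.5, "E2": 0.5}, effs)
        assert val == pytest.approx(0.5)

    def test_complex_role_excluded(self):
        effs = [nm.Effector("E1", 1), nm.Effector("E9", 9)]
        assert nm.tsignal({"E1": -1.0, "E9": 1.0}, effs) == 1.0

    def test_all_complex_is_an_error(self):
        with pytest.raises(ValidationError, match="no signed effectors"):
            nm.tsignal({"E": 1.0}, [nm.Effector("E", 9)])


class TestFitEnsemble:
    def test_zero_restraints_vacuous_accuracy(self, chain_net):
        ens = nm.fit_ensemble(chain_net, [], M=3, seed=1)
        assert ens.restraint_accuracy == 1.0
        assert ens.M == 3
        # weights sampled uniformly in [0, 1]
        for s in ens.solutions:
            assert np.all((s.weights >= 0) & (s.weights <= 1))

    def test_determinism_byte_identical(self, chain_net):
        a = nm.fit_ensemble(chain_net, [], M=5, seed=42)
        b = nm.fit_ensemble(chain_net, [], M=5, seed=42)
        for sa, sb in zip(a.solutions, b.solutions):
            assert np.array_equal(sa.weights, sb.weights)
            assert np.array_equal(sa.signals, sb.signals)
            assert sa.seed == sb.seed

    def test_unknown_restraint_protein_fails_before_fit(self, chain_net):
        bad = [nm.Restraint({"A": 1}, {"ZZ": 1})]
        with pytest.raises(ValidationError, match="ZZ"):
            nm.fit_ensemble(chain_net, bad, M=1, seed=0)

    def test_recovery_from_known_ground_truth(self):
        # restraints generated by a known weight assignment must be refittable
        cfg = nm.SynthConfig(
            n_nodes=120, seed=3, n_restraints=10, n_positive_rows=12,
            n_negative_rows=3, effectors_per_motive=(5, 5, 5, 5, 5),
        )
        net = nm.generate_interactome(cfg)
        gt = nm.generate_ground_truth_weights(net, cfg)
        _, restraints = nm.generate_truth_table(net, gt, cfg)
        assert len(restraints) == 10
        opt = nm.OptimizerConfig(steps=400)
        ens = nm.fit_ensemble(net, restraints, M=8, optimizer_cfg=opt, seed=3)
        assert ens.restraint_accuracy >= 0.9

    def test_drug_signals_attached(self, chain_net):
        drug = nm.DrugTargetProfile("d", {"A": -1})
        ens = nm.fit_ensemble(chain_net, [], M=2, seed=0, drug=drug)
        for s in ens.solutions:
            assert s.signals[chain_net.node_index["A"]] == -1.0


class TestMoA:
    def test_epsilon_saturation_empties_subnetwork(self, chain_net):
        drug = nm.DrugTargetProfile("d", {"A": -1})
        ens = nm.fit_ensemble(chain_net, [], M=3, seed=1, drug=drug)
        assert nm.moa_subnetwork(ens, epsilon=2.0).nodes == {}

    def test_chain_moa_contains_whole_path(self, chain_net):
        drug = nm.DrugTargetProfile("d", {"A": -1})
        ens = nm.fit_ensemble(chain_net, [], M=3, seed=1, drug=drug)
        sub = nm.moa_subnetwork(ens, epsilon=1e-6)
        assert set(sub.nodes) == {"A", "B", "C"}
        assert sub.nodes["A"] == -1.0
        assert len(sub.edges) == 2

    def test_clamped_target_always_in_own_moa(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            net = random_interactome(rng, n=10, p_edge=0.3)
            drug = nm.DrugTargetProfile("d", {net.nodes[2]: -1})
            ens = nm.fit_ensemble(net, [], M=2, seed=1, drug=drug)
            assert net.nodes[2] in nm.moa_subnetwork(ens).nodes


class TestSerialization:
    def test_ensemble_roundtrip(self, chain_net, tmp_path):
        drug = nm.DrugTargetProfile("d", {"A": -1})
        ens = nm.fit_ensemble(chain_net, [], M=4, seed=7, drug=drug)
        jp, sp = tmp_path / "e.json", tmp_path / "e.tsv"
        nm.save_ensemble(ens, jp, sp)
        back = nm.load_ensemble(chain_net, jp, sp)
        assert back.M == 4
        assert back.drug == drug
        assert np.allclose(back.signal_matrix(), ens.signal_matrix())
        for sa, sb in zip(ens.solutions, back.solutions):
            assert np.array_equal(sa.weights, sb.weights)
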