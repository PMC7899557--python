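"""Head-to-head motive/effector statistics, FDR behaviour and heatmap export."""

import numpy as np
import pytest

import netmoa as nm
from netmoa.compare import bh_adjust, welch_p
from netmoa.core import ValidationError
from netmoa.engine import ModelSolution


def _ensemble_with_signals(net, signal_columns, drug):
    """Hand-built ensemble whose solutions carry the given signal vectors."""
    sols = [
        ModelSolution(
            weights=np.ones(net.n_edges),
            signals=np.asarray(col, dtype=float),
            converged=True,
            seed=i,
        )
        for i, col in enumerate(signal_columns)
    ]
    return nm.ModelEnsemble(net, sols, 1.0, drug)


@pytest.fixture
def one_effector_net():
    net = nm.Interactome.from_edges([nm.Edge("T", "E", 1, 1.0)])
    return net


class TestBH:
    def test_hand_example(self):
        q = bh_adjust([0.01, 0.02, 0.04])
        assert np.allclose(q, [0.03, 0.03, 0.04])

    def test_monotone_and_dominating(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.uniform(0, 1, size=8)
            q = bh_adjust(p)
            assert np.all(q >= p - 1e-15)
            order = np.argsort(p)
            assert np.all(np.diff(q[order]) >= -1e-15)


class TestWelch:
    def test_degenerate_conventions(self):
        assert welch_p([1.0, 1.0], [1.0, 1.0])[1] == 1.0
        assert welch_p([1.0, 1.0], [0.0, 0.0])[1] == 0.0

    def test_matches_definition_on_real_samples(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 30), rng.normal(1, 2, 30)
        from scipy import stats
        t, p = welch_p(a, b)
        t2, p2 = stats.ttest_ind(a, b, equal_var=False)
        assert (t, p) == (float(t2), float(p2))


class TestCompareMotives:
    def test_identical_ensembles_all_ties(self, toy_two_drug):
        net, drugA, _, disease = toy_two_drug
        ens = nm.fit_ensemble(net, [], M=10, seed=1, drug=drugA)
        out = nm.compare_motives(ens, ens, disease)
        for m in out:
            assert m.q_value == 1.0
            assert m.winner is None
            assert m.pct_tie == 100.0

    def test_swap_symmetry(self, toy_two_drug):
        net, drugA, drugB, disease = toy_two_drug
        ensA = nm.fit_ensemble(net, [], M=15, seed=1, drug=drugA)
        ensB = nm.fit_ensemble(net, [], M=15, seed=2, drug=drugB)
        fwd = nm.compare_motives(ensA, ensB, disease)
        rev = nm.compare_motives(ensB, ensA, disease)
        for f, r in zip(fwd, rev):
            assert f.q_value == pytest.approx(r.q_value)
            assert f.pct_more_reversed_a == r.pct_more_reversed_b
            assert f.pct_more_reversed_b == r.pct_more_reversed_a
            if f.winner is not None:
                assert f.winner == r.winner  # same drug name wins either way

    def test_pct_triple_sums_to_100(self, mimic_ensembles, mimic_bundle):
        ensA, ensB = mimic_ensembles
        out = nm.compare_motives(ensA, ensB, mimic_bundle.disease)
        for m in out:
            total = m.pct_more_reversed_a + m.pct_more_reversed_b + m.pct_tie
            assert total == pytest.approx(100.0, abs=1e-9)

    def test_invalid_alpha(self, toy_two_drug):
        net, drugA, _, disease = toy_two_drug
        ens = nm.fit_ensemble(net, [], M=3, seed=1, drug=drugA)
        with pytest.raises(ValidationError):
            nm.compare_motives(ens, ens, disease, alpha=1.5)


class TestCompareEffectors:
    def test_identical_signals_tie(self, one_effector_net):
        net = one_effector_net
        cols = [[-1.0, -0.5]] * 5
        drug = nm.DrugTargetProfile("d", {"T": -1})
        ens = _ensemble_with_signals(net, cols, drug)
        out = nm.compare_effectors(ens, ens, [nm.Effector("E", 1)])
        assert out[0].more_reversed_by == "tie"
        assert out[0].relative_change_pct == 0.0

    def test_effector_reached_only_by_one_drug(self, toy_two_drug):
        net, drugA, drugB, disease = toy_two_drug
        ensA = nm.fit_ensemble(net, [], M=20, seed=1, drug=drugA)
        ensB = nm.fit_ensemble(net, [], M=20, seed=2, drug=drugB)
        out = nm.compare_effectors(ensA, ensB, disease.all_effectors)
        (c,) = out
        assert c.mean_reversal_b == 0.0
        assert c.mean_reversal_a > 0.0
        assert c.relative_change_pct == pytest.approx(100.0)
        assert c.more_reversed_by == "drugA"

    def test_significant_but_small_change_is_a_tie(self, one_effector_net):
        # 12% relative difference with tiny variance: q << 0.05 but below the
        # 20% change rule, so no call is made
        net = one_effector_net
        rng = np.random.default_rng(0)
        drugA = nm.DrugTargetProfile("drugA", {"T": -1})
        drugB = nm.DrugTargetProfile("drugB", {"T": -1})
        colsA = [[-1.0, -0.50 + 1e-4 * rng.standard_normal()] for _ in range(20)]
        colsB = [[-1.0, -0.44 + 1e-4 * rng.standard_normal()] for _ in range(20)]
        ensA = _ensemble_with_signals(net, colsA, drugA)
        ensB = _ensemble_with_signals(net, colsB, drugB)
        (c,) = nm.compare_effectors(ensA, ensB, [nm.Effector("E", 1)])
        assert c.q_value < 0.05
        assert c.relative_change_pct < 20.0
        assert c.more_reversed_by == "tie"

    def test_large_significant_change_is_called(self, one_effector_net):
        net = one_effector_net
        rng = np.random.default_rng(0)
        drugA = nm.DrugTargetProfile("drugA", {"T": -1})
        drugB = nm.DrugTargetProfile("drugB", {"T": -1})
        colsA = [[-1.0, -0.50 + 1e-4 * rng.standard_normal()] for _ in range(20)]
        colsB = [[-1.0, -0.20 + 1e-4 * rng.standard_normal()] for _ in range(20)]
        ensA = _ensemble_with_signals(net, colsA, drugA)
        ensB = _ensemble_with_signals(net, colsB, drugB)
        (c,) = nm.compare_effectors(ensA, ensB, [nm.Effector("E", 1)])
        assert c.more_reversed_by == "drugA"


class TestBrainPanel:
    def test_mimic_panel_report_has_eight_rows(self, mimic_ensembles, mimic_bundle):
        ensA, ensB = mimic_ensembles
        b = mimic_bundle
        comps = nm.compare_effectors(ensA, ensB, b.disease.all_effectors)
        rep = nm.brain_panel_report(
            comps, b.panel, ensA.drug.drug_name, ensB.drug.drug_name
        )
        assert len(rep.rows) == 8
        assert rep.count_a + rep.count_b + rep.count_tie == 8

    def test_panel_of_one_tie(self, one_effector_net):
        net = one_effector_net
        drug = nm.DrugTargetProfile("d", {"T": -1})
        ens = _ensemble_with_signals(net, [[-1.0, -0.5]] * 3, drug)
        comps = nm.compare_effectors(ens, ens, [nm.Effector("E", 1)])
        rep = nm.brain_panel_report(comps, nm.BrainPanel(("E",)), "d", "d")
        assert (rep.count_a, rep.count_b, rep.count_tie) == (0, 0, 1)

    def test_missing_panel_protein_is_an_error(self, one_effector_net):
        net = one_effector_net
        drug = nm.DrugTargetProfile("d", {"T": -1})
        ens = _ensemble_with_signals(net, [[-1.0, -0.5]] * 3, drug)
        comps = nm.compare_effectors(ens, ens, [nm.Effector("E", 1)])
        with pytest.raises(ValidationError, match="ZZ"):
            nm.brain_panel_report(comps, nm.BrainPanel(("ZZ",)), "d", "d")

    def test_engineered_panel_mostly_broad_only(self, toy_two_drug):
        # 6 of 8 panel effectors reachable only from the broad drug's target
        edges = [nm.Edge("TA", f"E{i}", 1, 1.0) for i in range(6)]
        edges += [nm.Edge("TB", "E6", 1, 1.0), nm.Edge("TB", "E7", 1, 1.0)]
        edges += [nm.Edge("TA", "E6", 1, 1.0), nm.Edge("TA", "E7", 1, 1.0)]
        net = nm.Interactome.from_edges(edges)
        drugA = nm.DrugTargetProfile("broad", {"TA": -1})
        drugB = nm.DrugTargetProfile("narrow", {"TB": -1})
        effs = [nm.Effector(f"E{i}", 1) for i in range(8)]
        ensA = nm.fit_ensemble(net, [], M=20, seed=4, drug=drugA)
        ensB = nm.fit_ensemble(net, [], M=20, seed=5, drug=drugB)
        comps = nm.compare_effectors(ensA, ensB, effs)
        rep = nm.brain_panel_report(
            comps, nm.BrainPanel(tuple(f"E{i}" for i in range(8))),
            "broad", "narrow",
        )
        assert rep.count_a == 6


class TestHeatmap:
    def test_shape_and_sidebar(self):
        net = nm.Interactome.from_edges(
            [nm.Edge("T", f"E{i}", 1, 1.0) for i in range(10)]
        )
        drugA = nm.DrugTargetProfile("a", {"T": -1})
        drugB = nm.DrugTargetProfile("b", {"T": -1})
        ensA = nm.fit_ensemble(net, [], M=3, seed=1, drug=drugA)
        ensB = nm.fit_ensemble(net, [], M=3, seed=2, drug=drugB)
        states = [1, -1, 9, 1, 1, -1, 9, 1, 1, 1]
        effs = [nm.Effector(f"E{i}", s) for i, s in enumerate(states)]
        df = nm.heatmap_matrix(ensA, ensB, effs)
        assert df.shape == (10, 1 + 3 + 3)
        assert list(df["pathological_state"]) == states

    def test_cells_match_solution_signals_exactly(self, chain_net):
        drug = nm.DrugTargetProfile("a", {"A": -1})
        ens = nm.fit_ensemble(chain_net, [], M=4, seed=9, drug=drug)
        effs = [nm.Effector("C", 1)]
        df = nm.heatmap_matrix(ens, ens, effs)
        ci = chain_net.node_index["C"]
        for m, sol in enumerate(ens.solutions):
            assert df.iloc[0, 1 + m] == sol.signals[ci]
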