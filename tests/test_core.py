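"""Network, profile, disease and restraint I/O plus neighborhood queries."""

import numpy as np
import pytest

import netmoa as nm
from netmoa.core import ParseError, ValidationError

from conftest import random_interactome


class TestInteractomeIO:
    def test_sif_parse(self, tmp_path):
        p = tmp_path / "net.sif"
        p.write_text("A\t+1\tB\nB\t-1\tC\n")
        net = nm.load_interactome(p)
        assert net.n_nodes == 3 and net.n_edges == 2
        assert net.edges[0] == nm.Edge("A", "B", 1, 1.0)
        assert net.edges[1] == nm.Edge("B", "C", -1, 1.0)

    def test_empty_file_is_an_error(self, tmp_path):
        p = tmp_path / "net.sif"
        p.write_text("")
        with pytest.raises(ParseError, match="no edges"):
            nm.load_interactome(p)

    def test_self_loop_roundtrip(self, tmp_path):
        p = tmp_path / "net.sif"
        p.write_text("A\t+1\tA\n")
        net = nm.load_interactome(p)
        assert net.edges == (nm.Edge("A", "A", 1, 1.0),)
        out = tmp_path / "again.sif"
        nm.write_interactome(net, out)
        assert nm.load_interactome(out).edges == net.edges

    @pytest.mark.parametrize("fmt", ["sif", "tsv", "graphml"])
    def test_roundtrip_preserves_edge_multiset(self, tmp_path, fmt):
        rng = np.random.default_rng(7)
        net = random_interactome(rng, n=10, p_edge=0.3)
        if fmt == "sif":  # SIF carries no weight column
            net = nm.Interactome(
                net.nodes,
                tuple(nm.Edge(e.source, e.target, e.sign, 1.0) for e in net.edges),
            )
        p = tmp_path / f"net.{fmt}"
        nm.write_interactome(net, p)
        back = nm.load_interactome(p)
        assert sorted(back.edges) == sorted(net.edges)

    def test_unknown_sign_token_rejected(self, tmp_path):
        p = tmp_path / "net.sif"
        p.write_text("A\t2\tB\n")
        with pytest.raises(ParseError, match="net.sif:1"):
            nm.load_interactome(p)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(nodes=("A",), edges=(nm.Edge("A", "B", 1, 1.0),)),  # dangling
            dict(nodes=("A", "B"), edges=(nm.Edge("A", "B", 2, 1.0),)),  # sign
            dict(nodes=("A", "B"), edges=(nm.Edge("A", "B", 1, 1.5),)),  # weight
            dict(
                nodes=("A", "B"),
                edges=(nm.Edge("A", "B", 1, 0.5), nm.Edge("A", "B", 1, 0.7)),
            ),  # duplicate triple
            dict(nodes=("A", "A"), edges=()),  # duplicate node
        ],
    )
    def test_construction_invariants(self, bad):
        with pytest.raises(ValidationError):
            nm.Interactome(**bad)

    def test_opposite_sign_multiedge_allowed(self):
        net = nm.Interactome(
            nodes=("A", "B"),
            edges=(nm.Edge("A", "B", 1, 0.5), nm.Edge("A", "B", -1, 0.5)),
        )
        assert net.n_edges == 2
        # opposing evidence of equal weight cancels in the adjacency
        assert net.signed_adjacency().toarray()[1, 0] == 0.0


class TestDrugProfiles:
    def test_six_target_inhibitor(self, tmp_path):
        rows = ["drug\tprotein\taction"]
        for t in ("ALK", "FLT3", "FER", "ROS1", "IGF1R", "EGFR"):
            rows.append(f"brigatinib\t{t}\t-1")
        p = tmp_path / "drug.tsv"
        p.write_text("\n".join(rows) + "\n")
        prof = nm.load_drug_profile(p)
        assert len(prof.targets) == 6
        assert set(prof.targets.values()) == {-1}

    def test_two_target_inhibitor(self, tmp_path):
        p = tmp_path / "drug.tsv"
        p.write_text("alectinib\tALK\t-1\nalectinib\tRET\t-1\n")
        prof = nm.load_drug_profile(p)
        assert prof.targets == {"ALK": -1, "RET": -1}

    def test_conflicting_duplicate_action_is_an_error(self, tmp_path):
        p = tmp_path / "drug.tsv"
        p.write_text("d\tALK\t+1\nd\tALK\t-1\n")
        with pytest.raises(ValidationError, match="conflicting"):
            nm.load_drug_profile(p)

    def test_profile_roundtrip(self, tmp_path):
        profs = [
            nm.DrugTargetProfile("a", {"X": -1, "Y": 1}),
            nm.DrugTargetProfile("b", {"X": -1}),
        ]
        p = tmp_path / "drugs.tsv"
        nm.write_drug_profiles(profs, p)
        assert nm.load_drug_profiles(p) == profs


class TestDisease:
    def test_two_motives(self, tmp_path):
        p = tmp_path / "dis.tsv"
        p.write_text("motive\tprotein\tstate\nm1\tE1\t1\nm1\tE2\t-1\nm2\tE3\t1\n")
        dis = nm.load_disease(p)
        assert set(dis.motives) == {"m1", "m2"}
        assert len(dis.all_effectors) == 3

    def test_complex_role_state_accepted(self, tmp_path):
        p = tmp_path / "dis.tsv"
        p.write_text("m1\tE1\t9\nm1\tE2\t1\n")
        dis = nm.load_disease(p)
        assert dis.motives["m1"][0].pathological_state == 9
        assert dis.signed_effectors("m1") == (nm.Effector("E2", 1),)

    def test_invalid_state_code(self, tmp_path):
        p = tmp_path / "dis.tsv"
        p.write_text("m1\tE1\t0\n")
        with pytest.raises(ValidationError):
            nm.load_disease(p)

    def test_duplicate_effector_within_motive(self):
        with pytest.raises(ValidationError, match="duplicated"):
            nm.DiseaseCharacterization(
                motives={"m": (nm.Effector("E", 1), nm.Effector("E", -1))}
            )

    def test_panel_must_be_effectors(self):
        dis = nm.DiseaseCharacterization(motives={"m": (nm.Effector("E", 1),)})
        nm.BrainPanel(("E",)).validate_against(dis)
        with pytest.raises(ValidationError):
            nm.BrainPanel(("E", "Z")).validate_against(dis)


class TestRestraints:
    def test_roundtrip(self, tmp_path):
        rs = [
            nm.Restraint({"A": 1}, {"C": -1}, "positive"),
            nm.Restraint({"B": -1}, {"C": 1, "A": -1}, "negative"),
        ]
        p = tmp_path / "r.json"
        nm.write_restraints(rs, p)
        assert nm.load_restraints(p) == rs

    def test_invalid_values(self):
        with pytest.raises(ValidationError):
            nm.Restraint({}, {"C": 1})
        with pytest.raises(ValidationError):
            nm.Restraint({"A": 2}, {"C": 1})


class TestNeighborhood:
    def test_radius_zero_is_identity(self, chain_net):
        assert nm.neighborhood(chain_net, {"A", "C"}, 0) == {"A", "C"}

    def test_chain_radius_one(self, chain_net):
        assert nm.neighborhood(chain_net, {"A"}, 1) == {"A", "B"}

    def test_saturation_covers_component(self, chain_net):
        assert nm.neighborhood(chain_net, {"A"}, 10) == {"A", "B", "C"}

    def test_undirected_reach(self, chain_net):
        # C reaches B against edge direction: "around" is undirected
        assert nm.neighborhood(chain_net, {"C"}, 1) == {"B", "C"}

    def test_missing_seed_listed(self, chain_net):
        with pytest.raises(ValidationError, match="ZZ"):
            nm.neighborhood(chain_net, {"A", "ZZ"}, 1)

    def test_monotone_in_radius(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            net = random_interactome(rng, n=12, p_edge=0.2)
            seeds = {net.nodes[0], net.nodes[5]}
            prev = nm.neighborhood(net, seeds, 0)
            for r in range(1, 5):
                cur = nm.neighborhood(net, seeds, r)
                assert prev <= cur
                prev = cur
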