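import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adrnet import LiftScore, build_network, disease_adr_scores
from adrnet.network import HeteroNetwork


def ls(a, ta, b, tb, value):
    return LiftScore(a=a, b=b, types=(ta, tb), value=value)


def random_network(seed, max_nodes=12):
    """A random typed weighted network with one disease node."""
    rng = np.random.default_rng(seed)
    n_drugs = int(rng.integers(1, max_nodes // 2))
    n_adrs = int(rng.integers(1, max_nodes - n_drugs - 1))
    drugs = [f"r{i}" for i in range(n_drugs)]
    adrs = [f"x{i}" for i in range(n_adrs)]
    net = HeteroNetwork()
    net.add_node("d", "disease")
    for r in drugs:
        net.add_node(r, "drug")
        if rng.random() < 0.7:
            net.add_link("d", "disease", r, "drug", float(rng.uniform(0.1, 5)))
    for x in adrs:
        net.add_node(x, "adr")
        for r in drugs:
            if rng.random() < 0.5:
                net.add_link(r, "drug", x, "adr", float(rng.uniform(0.1, 5)))
        if rng.random() < 0.3:
            net.add_link("d", "disease", x, "adr", float(rng.uniform(0.1, 5)))
    return net, drugs, adrs


def enumerate_scores(net, disease):
    """Independent oracle: enumerate every length-2 disease-drug-ADR path."""
    g = net.graph
    out = {}
    for adr in net.nodes("adr"):
        total = 0.0
        for drug in net.nodes("drug"):
            if g.has_edge(disease, drug) and g.has_edge(drug, adr):
                total += g.edges[disease, drug]["weight"] * g.edges[drug, adr]["weight"]
        out[adr] = total
    return out


class TestBuildNetwork:
    def test_node_counts_by_type(self):
        drugs = [f"r{i}" for i in range(55)]
        adrs = [f"x{i}" for i in range(199)]
        lifts = [ls("pd", "disease", r, "drug", 1.5) for r in drugs]
        lifts += [ls(drugs[i % 55], "drug", x, "adr", 2.0) for i, x in enumerate(adrs)]
        net = build_network(lifts)
        assert net.n_nodes == 255
        assert net.node_type_counts() == {"disease": 1, "drug": 55, "adr": 199}

    def test_empty_lift_list(self):
        net = build_network([])
        assert net.n_nodes == 0 and net.n_links == 0

    def test_min_weight_keeps_only_positive_associations(self):
        lifts = [
            ls("pd", "disease", "r1", "drug", 0.4),
            ls("pd", "disease", "r2", "drug", 1.0),
            ls("pd", "disease", "r3", "drug", 1.7),
        ]
        net = build_network(lifts, min_weight=1.0)
        assert net.n_links == 1 and net.weight("pd", "r3") == pytest.approx(1.7)

    def test_undefined_lifts_and_observed_nodes(self):
        lifts = [
            ls("pd", "disease", "r1", "drug", 2.0),
            LiftScore(a="pd", b="x1", types=("disease", "adr"), value=0.0, defined=False),
        ]
        net = build_network(lifts, nodes=[("x2", "adr")])
        assert net.n_links == 1
        assert set(net.nodes()) == {"pd", "r1", "x2"}


class TestDiseaseAdrScores:
    def test_two_bridges_sum_by_hand(self):
        net = HeteroNetwork()
        net.add_link("d", "disease", "r1", "drug", 2.0)
        net.add_link("r1", "drug", "x", "adr", 3.0)
        net.add_link("d", "disease", "r2", "drug", 1.0)
        net.add_link("r2", "drug", "x", "adr", 4.0)
        (score,) = disease_adr_scores(net, "d")
        assert score.score == pytest.approx(10.0)
        assert {p[0] for p in score.paths} == {"r1", "r2"}

    def test_no_bridge_scores_zero(self):
        net = HeteroNetwork()
        net.add_link("d", "disease", "r1", "drug", 2.0)
        net.add_node("x", "adr")
        (score,) = disease_adr_scores(net, "d")
        assert score.score == 0.0 and score.paths == ()

    def test_single_bridge_product(self):
        net = HeteroNetwork()
        net.add_link("d", "disease", "r1", "drug", 0.5)
        net.add_link("r1", "drug", "x", "adr", 0.5)
        (score,) = disease_adr_scores(net, "d")
        assert score.score == pytest.approx(0.25)

    def test_direct_disease_adr_link_excluded_but_reported(self):
        net = HeteroNetwork()
        net.add_link("d", "disease", "r1", "drug", 2.0)
        net.add_link("r1", "drug", "x", "adr", 3.0)
        net.add_link("d", "disease", "x", "adr", 7.0)
        (score,) = disease_adr_scores(net, "d")
        assert score.score == pytest.approx(6.0)
        assert score.direct_weight == pytest.approx(7.0)

    def test_missing_disease_errors(self):
        net = HeteroNetwork()
        net.add_node("x", "adr")
        with pytest.raises(ValueError, match="disease"):
            disease_adr_scores(net, "d")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_matches_exhaustive_path_enumeration(self, seed):
        net, _, _ = random_network(seed)
        got = {s.adr: s.score for s in disease_adr_scores(net, "d")}
        expected = enumerate_scores(net, "d")
        assert got.keys() == expected.keys()
        for adr in got:
            assert got[adr] == pytest.approx(expected[adr], abs=1e-12)

    def test_adding_bridge_never_decreases_scores(self):
        net, drugs, adrs = random_network(7)
        before = {s.adr: s.score for s in disease_adr_scores(net, "d")}
        net.add_link("d", "disease", "rnew", "drug", 1.5)
        net.add_link("rnew", "drug", adrs[0], "adr", 2.0)
        after = {s.adr: s.score for s in disease_adr_scores(net, "d")}
        assert all(after[a] >= before[a] for a in before)
        assert after[adrs[0]] == pytest.approx(before[adrs[0]] + 3.0)

    def test_removing_drug_never_increases_scores(self):
        net, drugs, _ = random_network(11)
        before = {s.adr: s.score for s in disease_adr_scores(net, "d")}
        net.graph.remove_node(drugs[0])
        after = {s.adr: s.score for s in disease_adr_scores(net, "d")}
        assert all(after[a] <= before[a] + 1e-12 for a in before)

    def test_insertion_order_invariance(self):
        links = [
            ("d", "disease", "r1", "drug", 2.0),
            ("r1", "drug", "x1", "adr", 3.0),
            ("d", "disease", "r2", "drug", 1.0),
            ("r2", "drug", "x1", "adr", 4.0),
            ("r2", "drug", "x2", "adr", 0.5),
        ]
        nets = []
        for order in (links, links[::-1]):
            net = HeteroNetwork()
            for link in order:
                net.add_link(*link)
            nets.append({s.adr: s.score for s in disease_adr_scores(net, "d")})
        assert nets[0] == nets[1]
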