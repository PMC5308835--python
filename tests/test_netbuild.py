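import math
from fractions import Fraction
from functools import lru_cache

import pytest
from scipy import stats

from coexnet.errors import ValidationError
from coexnet.ingest import InteractionEvidence
from coexnet.netbuild import (
    Network,
    NetworkConfig,
    build_networks,
    fisher_exact_right,
    hub_rank,
    log_fisher_exact_right,
    read_sif,
    score_network,
    unconnected_focus,
    write_network,
)


@lru_cache(maxsize=None)
def fisher_right_oracle(a, b, c, d):
    """Exhaustive enumeration of the hypergeometric right tail with exact
    rational arithmetic — independent of the log-space implementation."""
    N, K, n = a + b + c + d, a + c, a + b
    if N == 0:
        return 1.0
    total = Fraction(0)
    for k in range(a, min(K, n) + 1):
        total += Fraction(math.comb(K, k) * math.comb(N - K, n - k), math.comb(N, n))
    return float(total)


def evidence_from(pairs, relation="direct"):
    ev = InteractionEvidence()
    for a, b in pairs:
        ev.add(a, b, relation)
    return ev


def star(hub, leaves):
    return evidence_from((hub, leaf) for leaf in leaves)


def clique(nodes):
    return [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]]


class TestFisherRight:
    def test_zero_observed_gives_one(self):
        assert fisher_exact_right(0, 5, 3, 7) == pytest.approx(1.0)

    def test_balanced_table_matches_enumeration(self):
        assert fisher_exact_right(3, 1, 1, 3) == pytest.approx(
            fisher_right_oracle(3, 1, 1, 3), abs=1e-12
        )

    def test_random_tables_match_enumeration_and_scipy(self, rng):
        for _ in range(100):
            a, b, c, d = (int(v) for v in rng.integers(0, 25, size=4))
            p = fisher_exact_right(a, b, c, d)
            assert p == pytest.approx(fisher_right_oracle(a, b, c, d), abs=1e-12)
            # independent library cross-check of the same tail definition
            p_scipy = stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            assert p == pytest.approx(p_scipy, rel=1e-9, abs=1e-12)

    def test_monotone_nonincreasing_in_a_at_fixed_margins(self):
        # shift one unit along the diagonal: margins (10, 10, K, N-K) fixed
        ps = [fisher_exact_right(a, 10 - a, 8 - a, a + 2) for a in range(0, 9)]
        assert all(p1 >= p2 - 1e-15 for p1, p2 in zip(ps, ps[1:]))

    def test_log_tail_stays_finite_far_below_underflow(self):
        logp = log_fisher_exact_right(300, 0, 0, 10_000)
        assert math.isfinite(logp) and logp < -700  # exp() would underflow

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_right(-1, 2, 3, 4)


class TestBuildNetworks:
    def test_star_evidence_forms_single_network(self):
        ev = star("HUB", [f"L{i}" for i in range(1, 6)])
        nets = build_networks({f"L{i}" for i in range(1, 6)}, ev, NetworkConfig())
        assert len(nets) == 1
        net = nets[0]
        assert len(net.nodes) == 6 and net.n_internal_edges == 5
        assert net.degree("HUB") == 5
        assert "HUB" not in net.focus  # connector, not focus

    def test_disconnected_cliques_form_two_networks(self):
        nodes1, nodes2 = ["A1", "A2", "A3"], ["B1", "B2", "B3"]
        ev = evidence_from(clique(nodes1) + clique(nodes2))
        nets = build_networks(set(nodes1 + nodes2), ev, NetworkConfig())
        assert sorted(tuple(n.nodes) for n in nets) == [
            ("A1", "A2", "A3"), ("B1", "B2", "B3"),
        ]

    def test_forty_gene_clique_capped_at_35(self):
        genes = [f"F{i:02d}" for i in range(40)]
        ev = evidence_from(clique(genes))
        nets = build_networks(set(genes), ev, NetworkConfig(max_nodes=35))
        assert max(len(n.nodes) for n in nets) == 35
        assert all(len(n.nodes) <= 35 for n in nets)
        # every focus gene with evidence lands in exactly one network
        seen = [g for n in nets for g in n.focus]
        assert sorted(seen) == genes

    def test_focus_absent_from_evidence_reported_as_singleton(self):
        ev = star("HUB", ["L1", "L2"])
        assert unconnected_focus({"L1", "GHOST"}, ev) == ["GHOST"]
        nets = build_networks({"L1", "GHOST"}, ev, NetworkConfig())
        assert all("GHOST" not in n.nodes for n in nets)

    def test_induced_subgraph_property(self, rng):
        genes = [f"G{i:02d}" for i in range(30)]
        ev = InteractionEvidence()
        for i, a in enumerate(genes):
            for b in genes[i + 1:]:
                if rng.random() < 0.15:
                    ev.add(a, b)
        focus = set(rng.choice(genes, size=12, replace=False))
        nets = build_networks(focus, ev, NetworkConfig(max_nodes=10))
        for net in nets:
            members = set(net.nodes)
            for a in net.nodes:
                for b in net.nodes:
                    if a < b and ev.has_edge(a, b):
                        assert (a, b) in net.edges
            for (a, b) in net.edges:
                assert a in members and b in members
        focus_with_edges = {g for g in focus if ev.degree(g) > 0}
        assignments = [g for n in nets for g in n.focus]
        assert sorted(assignments) == sorted(focus_with_edges)

    def test_focus_preferred_over_better_connected_connector(self):
        # connector C touches all three members; focus gene F4 touches one.
        ev = evidence_from(
            [("F1", "F2"), ("F2", "F3"), ("F1", "F3"),
             ("C", "F1"), ("C", "F2"), ("C", "F3"), ("F4", "F1")]
        )
        nets = build_networks({"F1", "F2", "F3", "F4"}, ev, NetworkConfig(max_nodes=4))
        assert len(nets) == 1
        assert set(nets[0].nodes) == {"F1", "F2", "F3", "F4"}  # F4 in, C out

    def test_connectors_disabled(self):
        ev = star("HUB", ["L1", "L2", "L3"])
        nets = build_networks(
            {"L1", "L2", "L3"}, ev, NetworkConfig(allow_connectors=False)
        )
        # leaves only touch the hub, so each is its own single-node network
        assert all(len(n.nodes) == 1 for n in nets)
        assert len(nets) == 3

    def test_empty_focus_or_evidence_rejected(self):
        ev = star("H", ["L1"])
        with pytest.raises(ValidationError):
            build_networks(set(), ev, NetworkConfig())
        with pytest.raises(ValidationError):
            build_networks({"A"}, InteractionEvidence(), NetworkConfig())


class TestScoreNetwork:
    def _net(self, n_focus, n_conn):
        focus = [f"F{i}" for i in range(n_focus)]
        conn = [f"C{i}" for i in range(n_conn)]
        nodes = sorted(focus + conn)
        return Network(nodes=nodes, focus=set(focus), edges={})

    def test_matches_enumeration_on_toy_instance(self):
        net = self._net(8, 2)  # 10 nodes, 8 focus
        cfg = NetworkConfig(background_size=1000)
        score_network(net, n_focus_total=50, config=cfg)
        expected = fisher_right_oracle(8, 2, 42, 948)
        assert net.fisher_p == pytest.approx(expected, rel=1e-9)
        assert net.score == pytest.approx(-math.log10(expected), rel=1e-9)

    def test_all_focus_beats_half_focus_at_same_size(self):
        cfg = NetworkConfig(background_size=100)
        full = score_network(self._net(10, 0), 20, cfg)
        half = score_network(self._net(5, 5), 20, cfg)
        assert full.fisher_p < half.fisher_p

    def test_zero_focus_network_scores_zero(self):
        net = score_network(self._net(0, 6), 20, NetworkConfig(background_size=100))
        assert net.fisher_p == pytest.approx(1.0)
        assert net.score == pytest.approx(0.0)

    def test_adding_connected_focus_node_never_hurts(self):
        cfg = NetworkConfig(background_size=500)
        ps = [
            score_network(self._net(k, 10 - k), 30, cfg).fisher_p
            for k in range(0, 11)
        ]
        assert all(p1 >= p2 - 1e-15 for p1, p2 in zip(ps, ps[1:]))

    def test_score_invariant_under_relabeling(self):
        cfg = NetworkConfig(background_size=200)
        a = score_network(self._net(4, 3), 10, cfg)
        renamed = Network(
            nodes=sorted(f"X_{n}" for n in a.nodes),
            focus={f"X_{n}" for n in a.focus},
            edges={},
        )
        b = score_network(renamed, 10, cfg)
        assert a.fisher_p == b.fisher_p

    def test_inconsistent_background_rejected(self):
        with pytest.raises(ValidationError):
            score_network(self._net(5, 5), 20, NetworkConfig(background_size=12))
        with pytest.raises(ValidationError):
            score_network(self._net(5, 0), 3, NetworkConfig(background_size=100))


class TestHubRank:
    def test_star_hub_ranks_first(self):
        ev = star("HUB", [f"L{i}" for i in range(1, 7)])
        net = build_networks({f"L{i}" for i in range(1, 7)}, ev, NetworkConfig())[0]
        report = hub_rank(net)
        assert report.top_hub == "HUB"
        assert report.degree["HUB"] == 6

    def test_cycle_ties_break_lexicographically(self):
        nodes = ["N1", "N2", "N3", "N4"]
        ev = evidence_from([("N1", "N2"), ("N2", "N3"), ("N3", "N4"), ("N4", "N1")])
        net = build_networks(set(nodes), ev, NetworkConfig())[0]
        report = hub_rank(net)
        assert report.ranking == nodes  # all degree 2, all betweenness equal


class TestWriteNetwork:
    def _net(self):
        ev = evidence_from([("A", "B")])
        ev.add("B", "C", "indirect")
        net = build_networks({"A", "C"}, ev, NetworkConfig())[0]
        net.correlation_sign = {"A": 1, "C": -1}
        return net

    def test_graphml_deterministic_and_attributed(self, tmp_path):
        net = self._net()
        p1, p2 = tmp_path / "n1.graphml", tmp_path / "n2.graphml"
        write_network(net, p1, "graphml")
        write_network(net, p2, "graphml")
        assert p1.read_bytes() == p2.read_bytes()
        text = p1.read_text()
        assert "indirect" in text and "correlation_sign" in text

    def test_sif_roundtrip_preserves_edges(self, tmp_path):
        net = self._net()
        path = tmp_path / "n.sif"
        write_network(net, path, "sif")
        back = read_sif(path)
        assert back.relations == net.edges

    def test_empty_network_writes_valid_file(self, tmp_path):
        net = Network(nodes=["X"], focus={"X"}, edges={})
        write_network(net, tmp_path / "n.sif", "sif")
        assert (tmp_path / "n.sif").read_text() == "X\n"

    def test_tsv_writes_edge_and_node_tables(self, tmp_path):
        net = self._net()
        write_network(net, tmp_path / "n.tsv", "tsv")
        edges = (tmp_path / "n.tsv").read_text().splitlines()
        nodes = (tmp_path / "n.tsv.nodes.tsv").read_text().splitlines()
        assert edges[0] == "gene_a\tgene_b\trelation"
        assert len(edges) == 1 + net.n_internal_edges
        assert len(nodes) == 1 + len(net.nodes)
        assert any(line.startswith("C\t1\t-1") for line in nodes)

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            write_network(self._net(), tmp_path / "n.x", "xml")
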