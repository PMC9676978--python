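"""PPI graph construction, the six screening centralities, and median screening."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from herbnet.ppi_topology import (
    METRICS,
    ScoredEdge,
    ScreenConfig,
    build_network,
    compute_centralities,
    eigenvector_scores,
    load_packaged_table3,
    read_centrality_table,
    read_scored_edges,
    screen_core,
    write_centrality_table,
)

from _oracles import oracle_centralities, random_connected_graph


class TestBuildNetwork:
    def test_threshold_rule_hand_example(self):
        edges = [ScoredEdge("A", "B", 0.95), ScoredEdge("B", "C", 0.89), ScoredEdge("C", "D", 0.91)]
        g = build_network(edges, min_score=0.9)
        # B-C falls below the cut but both its endpoints keep another edge
        assert set(g.nodes) == {"A", "B", "C", "D"}
        assert {tuple(sorted(e)) for e in g.edges} == {("A", "B"), ("C", "D")}

    def test_all_below_threshold_gives_empty_network(self):
        g = build_network([ScoredEdge("A", "B", 0.5)], min_score=0.9)
        assert g.number_of_nodes() == 0

    def test_isolated_nodes_never_appear(self, rng):
        edges = [
            ScoredEdge(f"N{int(a)}", f"N{int(b)}", float(s))
            for a, b, s in zip(rng.integers(0, 60, 2000), rng.integers(60, 120, 2000), rng.uniform(0, 1, 2000))
        ]
        g = build_network(edges, min_score=0.9)
        # brute-force filter-and-prune oracle
        kept = {e.pair for e in edges if e.score >= 0.9}
        nodes = {v for pair in kept for v in pair}
        assert g.number_of_edges() == len(kept)
        assert set(g.nodes) == nodes
        assert min((d for _, d in g.degree), default=1) >= 1

    def test_score_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="score"):
            ScoredEdge("A", "B", 1.2)

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            ScoredEdge("A", "A", 0.5)

    def test_string_scale_autodetection(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("protein1\tprotein2\tcombined_score\nA\tB\t950\nB\tC\t400\n")
        edges = read_scored_edges(p)
        assert [e.score for e in edges] == [0.95, 0.4]


class TestComputeCentralities:
    def test_triangle_hand_enumeration(self):
        g = nx.complete_graph(3)
        t = compute_centralities(g)
        assert (t["dc"] == 2).all()
        assert (t["lac"] == 1.0).all()
        assert (t["nc"] == 2.0).all()
        assert np.allclose(t["ec"], 1.0)  # symmetry: all nodes maximal

    def test_star_center_and_leaves(self):
        g = nx.star_graph(4)
        t = compute_centralities(g)
        assert t.loc[0, "lac"] == 0.0  # leaves induce no edges
        assert (t.loc[1:, "bc"] == 0.0).all()  # leaves lie on no shortest paths
        assert t.loc[0, "cc"] == t["cc"].max()  # closeness maximal at the center

    def test_matches_bruteforce_oracle_on_random_graphs(self, rng):
        for _ in range(30):
            g = random_connected_graph(rng)
            table = compute_centralities(g)
            oracle = oracle_centralities(g)
            for m in METRICS:
                for v in g.nodes:
                    assert table.loc[v, m] == pytest.approx(oracle[m][v], abs=1e-9), (m, v)

    def test_relabeling_invariance_of_local_metrics(self, rng):
        g = random_connected_graph(rng)
        perm = {v: f"X{i}" for i, v in enumerate(rng.permutation(list(g.nodes)))}
        h = nx.relabel_nodes(g, perm)
        tg, th = compute_centralities(g), compute_centralities(h)
        for m in ("dc", "lac", "nc"):
            for v in g.nodes:
                assert tg.loc[v, m] == pytest.approx(th.loc[perm[v], m])

    def test_power_iteration_agrees_with_dense_eigensolver(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 51))
            g = nx.gnp_random_graph(n, 0.2, seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0 or not nx.is_connected(g):
                continue
            a = nx.to_numpy_array(g)
            w, vecs = np.linalg.eigh(a)
            ref = np.abs(vecs[:, int(np.argmax(w))])
            ref /= ref.max()
            assert np.abs(eigenvector_scores(g, nodelist=list(g.nodes)) - ref).max() < 1e-8

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            compute_centralities(nx.Graph())


class TestScreenCore:
    def test_vertex_transitive_graph_is_terminal(self):
        result = screen_core(nx.cycle_graph(6))
        assert result.terminal
        assert len(result.retained) == 6  # the round's input is returned intact

    def test_retained_strictly_exceed_recorded_medians(self, rng):
        for _ in range(30):
            g = random_connected_graph(rng)
            result = screen_core(g, ScreenConfig(rounds="until-stable"))
            assert set(result.retained) <= set(g.nodes)
            for rnd in result.rounds:
                if result.terminal and rnd is result.rounds[-1]:
                    continue
                for v in rnd.retained:
                    for m in METRICS:
                        assert rnd.table.loc[v, m] > rnd.medians[m]

    def test_planted_core_recovery(self):
        from herbnet.synthetic_data import SynthConfig, gen_ppi

        hits = total = 0
        for seed in range(50):
            cfg = SynthConfig(seed=seed, ppi_n_core=20, ppi_n_periphery=80)
            edges, core = gen_ppi(cfg)
            g = build_network(edges, min_score=0.9)
            result = screen_core(g)
            retained = set(result.retained)
            hits += len(retained & set(core))
            total += len(retained)
        assert total > 0
        assert hits / total >= 0.90  # >= 90% of retained nodes are planted core

    def test_five_metric_subset_supported(self, rng):
        g = random_connected_graph(rng)
        cfg = ScreenConfig(metrics=("dc", "cc", "ec", "lac", "nc"))
        result = screen_core(g, cfg)
        assert set(result.rounds[0].medians) == {"dc", "cc", "ec", "lac", "nc"}

    def test_induced_subgraph_shrinks_monotonically(self, rng):
        g = random_connected_graph(rng, n_max=20, n_min=10)
        result = screen_core(g, ScreenConfig(rounds="until-stable"))
        sizes = [len(r.retained) for r in result.rounds]
        assert sizes == sorted(sizes, reverse=True)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ScreenConfig(metrics=())
        with pytest.raises(ValueError):
            ScreenConfig(rounds=0)
        with pytest.raises(ValueError):
            ScreenConfig(metrics=("dc", "zz"))


class TestCentralityTableIO:
    def test_packaged_core_table(self):
        t3 = load_packaged_table3()
        assert len(t3) == 44
        assert t3["dc"].max() == 43
        assert t3["dc"].idxmax() == "HSP90AA1"

    def test_roundtrip_preserves_report_column_order(self, tmp_path, rng):
        g = random_connected_graph(rng)
        table = compute_centralities(g)
        p = tmp_path / "cent.csv"
        write_centrality_table(table, p)
        header = p.read_text().splitlines()[0]
        assert header == "name,Betweenness,Closeness,Degree,Eigenvector,LAC,Network"
        again = read_centrality_table(p)
        pd.testing.assert_frame_equal(
            again[list(METRICS)].sort_index(), table.sort_index(), check_exact=False)
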