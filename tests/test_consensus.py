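import networkx as nx
import numpy as np
import pandas as pd
import pytest

from hifnet import (
    ExpressionMatrix,
    ProbeAnnotation,
    consensus_edges,
    detect_modules,
    differential_expression,
    extract_apl_subnetwork,
    hub_table,
)
from hifnet.stats import bh_adjust


def brute_force_bh(p):
    """Step-up BH computed literally from its definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


class TestBHAdjustment:
    def test_worked_example(self):
        q = bh_adjust([0.001, 0.011, 0.02, 0.04])
        np.testing.assert_allclose(q, [0.004, 0.022, 0.0267, 0.04], atol=5e-5)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), rtol=1e-12)


def labeled_matrix(data, probes, case_n, rest_n, case="M3", rest="M1"):
    samples = [f"c{i}" for i in range(case_n)] + [f"r{i}" for i in range(rest_n)]
    labels = {s: (case if s.startswith("c") else rest) for s in samples}
    return ExpressionMatrix(pd.DataFrame(data, index=probes, columns=samples), labels)


class TestDifferentialExpression:
    def test_direction_flips_under_negation(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(30, 40))
        data[:10, :20] += 2.0
        m = labeled_matrix(data, [f"p{i}" for i in range(30)], 20, 20)
        neg = labeled_matrix(-data, m.probe_ids, 20, 20)
        de = differential_expression(m, "M3")
        de_neg = differential_expression(neg, "M3")
        np.testing.assert_allclose(de["p"], de_neg["p"])
        flip = {"up": "down", "down": "up", "ns": "ns"}
        assert [flip[d] for d in de["direction"]] == list(de_neg["direction"])

    def test_null_discovery_fraction_controlled(self):
        rng = np.random.default_rng(2)
        fracs = []
        for _ in range(10):
            m = labeled_matrix(rng.normal(size=(200, 40)),
                               [f"p{i}" for i in range(200)], 20, 20)
            de = differential_expression(m, "M3")
            fracs.append(float((de["q"] < 0.05).mean()))
        assert np.mean(fracs) <= 0.05

    def test_degenerate_group_is_an_error(self):
        m = labeled_matrix(np.zeros((3, 5)), list("abc"), 1, 4)
        with pytest.raises(ValueError, match=">=2 samples"):
            differential_expression(m, "M3")


def graph_from(edges, mi=0.5, p=1e-6):
    g = nx.Graph()
    for u, v in edges:
        g.add_edge(u, v, mi=mi, p=p)
    return g


class TestConsensusEdges:
    def test_undirected_intersection(self):
        a = graph_from([("A", "B"), ("B", "C")])
        b = graph_from([("C", "B"), ("C", "D")])
        cons = consensus_edges(a, b)
        assert set(map(frozenset, cons.edges)) == {frozenset({"B", "C"})}
        assert set(cons.nodes) == {"B", "C"}

    def test_subset_of_each_input_and_commutative(self):
        rng = np.random.default_rng(3)
        nodes = [f"n{i}" for i in range(15)]
        a = graph_from(
            {tuple(sorted(rng.choice(nodes, 2, replace=False))) for _ in range(25)})
        b = graph_from(
            {tuple(sorted(rng.choice(nodes, 2, replace=False))) for _ in range(25)})
        ab = consensus_edges(a, b)
        ba = consensus_edges(b, a)
        assert set(map(frozenset, ab.edges)) <= set(map(frozenset, a.edges))
        assert ab.number_of_edges() <= min(a.number_of_edges(), b.number_of_edges())
        assert set(map(frozenset, ab.edges)) == set(map(frozenset, ba.edges))


def de_frame(nodes, q, delta=1.0):
    q = np.asarray(q, dtype=float)
    delta = np.broadcast_to(np.asarray(delta, dtype=float), q.shape)
    direction = np.where(q < 0.05, np.where(delta > 0, "up", "down"), "ns")
    return pd.DataFrame(
        {"t": np.zeros_like(q), "p": q / 2, "q": q, "delta": delta,
         "direction": direction},
        index=pd.Index(nodes, name="probe"),
    )


def identity_annotation(nodes):
    return ProbeAnnotation({n: f"G_{n}" for n in nodes})


class TestExtractSubnetwork:
    def test_component_size_rule(self):
        chain = [(f"g{i}", f"g{i+1}") for i in range(11)]  # 12-gene component
        cons = graph_from(chain + [("x1", "x2")])
        nodes = sorted(cons.nodes)
        de = de_frame(nodes, np.full(len(nodes), 0.01))
        sub = extract_apl_subnetwork(cons, de, de, identity_annotation(nodes))
        assert set(sub.nodes) == {f"g{i}" for i in range(12)}
        assert sub.components["n_genes"].tolist() == [12]

    def test_node_must_be_significant_in_both_cohorts(self):
        cons = graph_from([(f"g{i}", f"g{i+1}") for i in range(12)])
        nodes = sorted(cons.nodes)
        de_a = de_frame(nodes, np.full(len(nodes), 0.01))
        q_b = np.full(len(nodes), 0.01)
        q_b[nodes.index("g5")] = 0.2
        de_b = de_frame(nodes, q_b)
        sub = extract_apl_subnetwork(cons, de_a, de_b, identity_annotation(nodes),
                                     min_component_genes=3)
        assert "g5" not in sub.nodes

    def test_duplicated_cohort_equals_single_cohort_pruning(self):
        cons = graph_from([(f"g{i}", f"g{i+1}") for i in range(20)])
        nodes = sorted(cons.nodes)
        rng = np.random.default_rng(4)
        de = de_frame(nodes, rng.uniform(0, 0.1, len(nodes)),
                      delta=rng.choice([-1.0, 1.0], len(nodes)))
        ann = identity_annotation(nodes)
        dup = extract_apl_subnetwork(cons, de, de, ann, min_component_genes=2)
        keep = [n for n in cons.nodes if de.loc[n, "q"] < 0.05]
        single = cons.subgraph(keep)
        comps = [c for c in nx.connected_components(single) if len(c) > 2]
        expected = set().union(*comps) if comps else set()
        assert set(dup.nodes) == expected

    def test_component_filter_only_shrinks(self):
        cons = graph_from([("a", "b"), ("c", "d"), ("d", "e")])
        nodes = sorted(cons.nodes)
        de = de_frame(nodes, np.full(len(nodes), 0.01))
        ann = identity_annotation(nodes)
        unfiltered = extract_apl_subnetwork(cons, de, de, ann, min_component_genes=0)
        filtered = extract_apl_subnetwork(cons, de, de, ann, min_component_genes=2)
        assert set(filtered.nodes) <= set(unfiltered.nodes)


class TestHubTable:
    def test_star_degrees_and_worst_p(self):
        g = graph_from([("hub", f"leaf{i}") for i in range(5)])
        nodes = sorted(g.nodes)
        de_a = de_frame(nodes, np.full(len(nodes), 0.01))
        de_a["p"] = 1e-8
        de_b = de_frame(nodes, np.full(len(nodes), 0.01))
        de_b["p"] = 1e-3
        hubs = hub_table(g, de_a, de_b)
        assert hubs.iloc[0]["node"] == "hub"
        assert hubs.iloc[0]["degree"] == 5
        assert set(hubs["degree"][1:]) == {1}
        assert (hubs["worst_p"] == 1e-3).all()

    def test_missing_node_is_an_error(self):
        g = graph_from([("a", "b")])
        de = de_frame(["a"], [0.01])
        with pytest.raises(KeyError, match="missing from a differential"):
            hub_table(g, de, de)

    def test_planted_apl_anchor_is_top_hub(self, default_run):
        _, annotation, _, truth, res = default_run
        hubs = hub_table(res.consensus, res.de_a, res.de_b, annotation)
        top = hubs.iloc[0]
        down_anchors = truth.modules["apl_down"] & truth.modules["seed"]
        up_anchors = truth.modules["apl_up"] & truth.modules["seed"]
        assert top["gene"] in down_anchors | up_anchors
        assert top["worst_p"] < 0.05


class TestDetectModules:
    def test_two_disjoint_triangles(self):
        g = graph_from([("a", "b"), ("b", "c"), ("c", "a"),
                        ("x", "y"), ("y", "z"), ("z", "x")])
        labels, sizes = detect_modules(g)
        assert sizes["n_probes"].tolist() == [3, 3]
        assert labels["a"] == labels["b"] == labels["c"]
        assert labels["a"] != labels["x"]

    def test_sizes_partition_the_nodes(self, default_run):
        *_, res = default_run
        labels, sizes = detect_modules(res.consensus)
        assert sizes["n_probes"].sum() == res.consensus.number_of_nodes()
        assert len(labels) == res.consensus.number_of_nodes()

    def test_recovers_planted_star_gene_sets(self, small_cohorts, small_config):
        from hifnet import SeedList, calibrate_null, infer_relevance_network

        em_a, _, annotation, seeds, truth = small_cohorts
        # restrict to two specific non-APL stars plus background probes
        anchors = sorted(truth.modules["seed"] - truth.apl_genes)[:2]
        genes = set(anchors)
        for m, a in truth.member_of.items():
            if a in anchors:
                genes.add(m)
        probes = [p for p in em_a.probe_ids
                  if annotation.gene_of(p) in genes
                  or annotation.gene_of(p) in truth.modules["background"]]
        sub = em_a.subset_probes(probes)
        cal = calibrate_null(sub, n_pairs=2000, rng_seed=9)
        seed_list = SeedList(genes=anchors).resolve(annotation, sub)
        net = infer_relevance_network(sub, seed_list, 1e-6, cal)
        _, sizes = detect_modules(net, annotation)
        assert len(sizes) == 2
        comps = [set(c) for c in nx.connected_components(net)]
        gene_sets = [{annotation.gene_of(p) for p in c} for c in comps]
        expected = [
            {a} | {m for m, anc in truth.member_of.items() if anc == a}
            for a in anchors
        ]
        assert sorted(map(sorted, gene_sets)) == sorted(map(sorted, expected))
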