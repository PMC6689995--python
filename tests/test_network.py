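"""Co-expression graph construction and Markov clustering."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from atlasforge.models import ExpressionMatrix
from atlasforge.network import (
    CoexpressionGraph,
    RawPartition,
    correlation_graph,
    expression_filter,
    mcl_cluster,
    postprocess_clusters,
    threshold_scan,
    tissue_average,
)


def make_expr(values, samples, tissues, genes=None):
    genes = genes or [f"g{i}" for i in range(len(values))]
    data = pd.DataFrame(values, index=genes, columns=samples, dtype=float)
    meta = pd.DataFrame({"tissue": tissues}, index=pd.Index(samples, name="sample_id"))
    return ExpressionMatrix(data=data, metadata=meta)


# ----------------------------------------------------------- tissue average

def test_tissue_average_means_and_single_replicates():
    expr = make_expr([[10, 20, 7]], ["a1", "a2", "b1"], ["A", "A", "B"])
    tm = tissue_average(expr)
    assert tm.loc["g0", "A"] == 15
    assert tm.loc["g0", "B"] == 7
    assert list(tm.columns) == ["A", "B"]


def test_tissue_average_matches_groupby_oracle():
    rng = np.random.default_rng(2)
    samples = [f"s{i}" for i in range(12)]
    tissues = [f"T{i // 3}" for i in range(12)]
    expr = make_expr(rng.uniform(0, 100, size=(50, 12)), samples, tissues)
    tm = tissue_average(expr)
    oracle = expr.data.T.groupby(pd.Series(tissues, index=samples)).mean().T
    pd.testing.assert_frame_equal(tm, oracle[tm.columns], check_names=False)


# -------------------------------------------------------- expression filter

def test_expression_filter_is_strict_at_the_threshold():
    tm = pd.DataFrame({"A": [10.0, 10.5, 0.0], "B": [10.0, 0.0, 3.0]},
                      index=["exact", "above", "below"])
    kept = expression_filter(tm, min_tpm=10.0)
    assert list(kept.index) == ["above"]
    with pytest.raises(ValueError, match="lower the threshold"):
        expression_filter(tm, min_tpm=1e9)


def test_expression_filter_matches_rowmax_oracle():
    rng = np.random.default_rng(3)
    tm = pd.DataFrame(rng.uniform(0, 30, size=(80, 6)))
    kept = expression_filter(tm, min_tpm=10.0)
    oracle = [g for g in tm.index if tm.loc[g].max() > 10.0]
    assert list(kept.index) == oracle


# -------------------------------------------------------- correlation graph

def test_proportional_profiles_give_perfect_correlation():
    tm = pd.DataFrame({"t1": [2.0, 1.0], "t2": [4.0, 2.0], "t3": [6.0, 3.0]},
                      index=["a", "b"])
    cg = correlation_graph(tm, r_min=1.0)
    assert cg.graph.has_edge("a", "b")
    assert cg.graph["a"]["b"]["weight"] == pytest.approx(1.0)


def test_constant_profile_gene_is_isolated_and_reported():
    tm = pd.DataFrame({"t1": [5.0, 1.0, 2.0], "t2": [5.0, 2.0, 4.0],
                       "t3": [5.0, 3.0, 6.0]}, index=["flat", "a", "b"])
    cg = correlation_graph(tm, r_min=0.8)
    assert cg.zero_variance == ["flat"]
    assert cg.graph.degree("flat") == 0
    assert cg.graph.has_edge("a", "b")


def test_adjacency_matches_direct_formula_oracle():
    rng = np.random.default_rng(7)
    tm = pd.DataFrame(rng.uniform(0, 50, size=(20, 8)),
                      index=[f"g{i}" for i in range(20)])
    cg = correlation_graph(tm, r_min=0.5)
    genes = list(tm.index)
    oracle_edges = set()
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            x, y = tm.iloc[i].to_numpy(), tm.iloc[j].to_numpy()
            r = (((x - x.mean()) * (y - y.mean())).mean() / (x.std() * y.std()))
            if r >= 0.5:
                oracle_edges.add(frozenset({genes[i], genes[j]}))
    got = {frozenset({a, b}) for a, b in cg.graph.edges}
    assert got == oracle_edges


def test_correlation_graph_input_validation():
    tm = pd.DataFrame(np.ones((4, 2)))
    with pytest.raises(ValueError, match="3 tissues"):
        correlation_graph(tm)
    tm3 = pd.DataFrame(np.ones((1, 5)))
    with pytest.raises(ValueError, match="2 genes"):
        correlation_graph(tm3)
    with pytest.raises(ValueError, match="r_min"):
        correlation_graph(pd.DataFrame(np.ones((4, 4))), r_min=0.0)


# ---------------------------------------------------------------------- MCL

def graph_from_nx(g, r_min=0.5):
    return CoexpressionGraph(graph=g, r_min=r_min, zero_variance=[])


def test_two_disjoint_cliques_form_two_clusters():
    g = nx.Graph()
    for offset, names in ((0, "abcd"), (1, "wxyz")):
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                g.add_edge(a, b, weight=0.9)
    raw = mcl_cluster(graph_from_nx(g))
    assert sorted(map(sorted, raw.clusters)) == [list("abcd"), list("wxyz")]


def test_complete_graph_is_one_cluster():
    g = nx.complete_graph(5)
    nx.set_edge_attributes(g, 1.0, "weight")
    raw = mcl_cluster(graph_from_nx(g))
    assert len(raw.clusters) == 1
    assert raw.clusters[0] == frozenset(range(5))


def planted_graph(seed, n_modules=3, module_size=20, p_in=0.9, p_out=0.04):
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    labels = {}
    nodes = [f"n{i:03d}" for i in range(n_modules * module_size)]
    g.add_nodes_from(nodes)
    for i, a in enumerate(nodes):
        labels[a] = i // module_size
        for b in nodes[i + 1:]:
            same = labels[a] == (nodes.index(b) // module_size)
            p = p_in if same else p_out
            if rng.random() < p:
                g.add_edge(a, b, weight=rng.uniform(0.85, 1.0))
    return g, labels


def reference_mcl(g, inflation=2.2, expansion=2, prune=1e-5, tol=1e-6, max_iter=200):
    """Independent sparse-matrix MCL; clusters via connected components."""
    nodes = sorted(g.nodes)
    pos = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = sp.lil_matrix((n, n))
    for a, b, d in g.edges(data=True):
        m[pos[a], pos[b]] = d["weight"]
        m[pos[b], pos[a]] = d["weight"]
    m.setdiag(1.0)
    m = sp.csr_matrix(sp.csr_matrix(m).multiply(1.0 / sp.csr_matrix(m).sum(axis=0)))
    for _ in range(max_iter):
        prev = m.copy()
        m = (m ** expansion).power(inflation)
        m = sp.csr_matrix(m.multiply(1.0 / m.sum(axis=0)))
        m.data[m.data < prune] = 0.0
        m.eliminate_zeros()
        m = sp.csr_matrix(m.multiply(1.0 / m.sum(axis=0)))
        if abs(m - prev).max() < tol:
            break
    comp = nx.Graph()
    comp.add_nodes_from(range(n))
    rows, cols = m.nonzero()
    comp.add_edges_from(zip(rows, cols))
    return {frozenset(nodes[i] for i in c) for c in nx.connected_components(comp)}


@pytest.mark.parametrize("seed", range(10))
def test_mcl_matches_independent_reference_on_planted_graphs(seed):
    g, _ = planted_graph(seed)
    raw = mcl_cluster(graph_from_nx(g), inflation=2.2)
    assert set(raw.clusters) == reference_mcl(g, inflation=2.2)


def test_mcl_recovers_planted_modules_and_stays_stochastic():
    g, labels = planted_graph(99)
    raw = mcl_cluster(graph_from_nx(g), inflation=2.2)
    assert raw.converged
    assert max(raw.column_sum_errors) < 1e-9
    modules = {}
    for node, lab in labels.items():
        modules.setdefault(lab, set()).add(node)
    assert set(raw.clusters) == {frozenset(v) for v in modules.values()}


def test_mcl_partition_covers_all_nodes_disjointly():
    g, _ = planted_graph(3, p_out=0.15)
    raw = mcl_cluster(graph_from_nx(g))
    seen = [n for c in raw.clusters for n in c]
    assert len(seen) == len(set(seen)) == g.number_of_nodes()


def test_mcl_input_validation():
    with pytest.raises(ValueError, match="empty graph"):
        mcl_cluster(graph_from_nx(nx.Graph()))
    g = nx.complete_graph(3)
    nx.set_edge_attributes(g, 1.0, "weight")
    with pytest.raises(ValueError, match="inflation"):
        mcl_cluster(graph_from_nx(g), inflation=1.0)


# ------------------------------------------------------------ postprocessing

def raw_partition(clusters):
    return RawPartition(clusters=[frozenset(c) for c in clusters],
                        converged=True, n_iterations=1, column_sum_errors=[0.0])


def test_small_clusters_are_excluded_and_survivors_renumbered():
    raw = raw_partition([
        [f"a{i}" for i in range(10)], ["x1", "x2", "x3", "x4"],
        [f"b{i}" for i in range(7)]])
    assigned = postprocess_clusters(raw, min_size=5)
    assert assigned.sizes == [10, 7]
    assert assigned.small == frozenset({"x1", "x2", "x3", "x4"})
    assert assigned.all_genes() == frozenset(
        n for c in raw.clusters for n in c)


def test_numbering_matches_sort_oracle():
    rng = np.random.default_rng(11)
    names = [f"g{i:03d}" for i in range(60)]
    rng.shuffle(names)
    sizes = [9, 9, 14, 6, 5, 17]
    clusters, start = [], 0
    for s in sizes:
        clusters.append(names[start:start + s])
        start += s
    assigned = postprocess_clusters(raw_partition(clusters), min_size=5)
    oracle = sorted((frozenset(c) for c in clusters),
                    key=lambda c: (-len(c), min(c)))
    assert assigned.clusters == oracle


def test_threshold_scan_reports_nodes_and_edges():
    rng = np.random.default_rng(13)
    tm = pd.DataFrame(rng.uniform(0, 50, size=(30, 8)))
    scan = threshold_scan(tm, [0.5, 0.7, 0.9])
    assert list(scan.columns) == ["r_min", "nodes", "edges"]
    assert scan.edges.is_monotonic_decreasing
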