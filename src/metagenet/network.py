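"""Signed network construction and topology analysis.

An undirected edge joins genes i, j iff the direct-dependency score exceeds
the (RMT-chosen) threshold in magnitude AND the FDR-adjusted correlation
p-value is below ``q_max``. Edges carry the sign of the correlation; genes
with no edge are not network nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .correlation import CorrelationResult
from .data_model import Prevalence, PrevalenceClass


def build_network(
    corr: CorrelationResult,
    threshold: float,
    q_max: float = 0.05,
    metadata: pd.DataFrame | None = None,
    prevalence: dict[str, PrevalenceClass] | None = None,
    matrix: str = "deconvolved",
    weights: np.ndarray | None = None,
) -> nx.Graph:
    """Threshold + FDR edge rule on a correlation result.

    ``matrix`` selects which score is thresholded: ``"deconvolved"`` (default;
    requires :func:`metagenet.correlation.deconvolve` to have run, possibly
    rescaled via ``weights``) or ``"rho"`` (raw Spearman). Node attributes
    ``prevalence``, ``is_duf`` and ``category`` are attached when given.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    if weights is not None:
        M = np.asarray(weights, dtype=float)
    elif matrix == "deconvolved":
        if corr.deconvolved_rho is None:
            raise ValueError("correlation result has no deconvolved matrix")
        M = corr.deconvolved_rho
    elif matrix == "rho":
        M = corr.rho
    else:
        raise ValueError(f"unknown matrix {matrix!r}")
    if corr.q is None:
        raise ValueError("q-values not computed")
    n = len(corr.genes)
    if M.shape != (n, n) or corr.q.shape != (n, n):
        raise ValueError("matrix shapes do not match the gene list")

    meta_idx: dict[str, tuple[str, bool]] = {}
    if metadata is not None:
        for row in metadata.itertuples(index=False):
            meta_idx[row.gene] = (row.category, bool(row.is_duf))

    g = nx.Graph(threshold=float(threshold), q_max=float(q_max))
    iu, ju = np.triu_indices(n, k=1)
    hit = (np.abs(M[iu, ju]) > threshold) & (corr.q[iu, ju] < q_max)
    for i, j in zip(iu[hit], ju[hit]):
        a, b = corr.genes[i], corr.genes[j]
        w = float(M[i, j])
        g.add_edge(a, b, weight=w, sign="+" if w > 0 else "-", rho=float(corr.rho[i, j]))
    for node in g.nodes:
        if prevalence is not None and node in prevalence:
            g.nodes[node]["prevalence"] = prevalence[node].label.value
        cat, duf = meta_idx.get(node, ("", False))
        g.nodes[node]["category"] = cat
        g.nodes[node]["is_duf"] = duf
    return g


def subnetwork(net: nx.Graph, prevalence_class: str) -> nx.Graph:
    """Induced subgraph on one prevalence class (both endpoints in class)."""
    if prevalence_class not in (Prevalence.CORE.value, Prevalence.NONCORE.value):
        raise ValueError(f"unknown prevalence class {prevalence_class!r}")
    nodes = [v for v, d in net.nodes(data=True) if d.get("prevalence") == prevalence_class]
    return net.subgraph(nodes).copy()


def edge_partition(net: nx.Graph) -> dict[str, int]:
    """Edge counts by endpoint prevalence: core-core / noncore-noncore / core-noncore."""
    counts = {"core-core": 0, "noncore-noncore": 0, "core-noncore": 0}
    for a, b in net.edges:
        ca = net.nodes[a].get("prevalence")
        cb = net.nodes[b].get("prevalence")
        if ca is None or cb is None:
            raise ValueError(f"node without prevalence class on edge ({a}, {b})")
        if ca == cb == "core":
            counts["core-core"] += 1
        elif ca == cb == "noncore":
            counts["noncore-noncore"] += 1
        else:
            counts["core-noncore"] += 1
    return counts


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    n_positive: int
    n_negative: int
    density: float
    clustering_mean_local: float
    clustering_transitivity: float
    diameter_lcc: int
    degree_sequence: list[int]
    powerlaw_r2: float | None
    powerlaw_slope: float | None


def sign_counts(net: nx.Graph) -> tuple[int, int]:
    pos = sum(1 for _, _, d in net.edges(data=True) if d["sign"] == "+")
    return pos, net.number_of_edges() - pos


def topology_summary(net: nx.Graph) -> TopologySummary:
    """Scalar topology descriptors (sign-blind, unweighted where relevant).

    The clustering coefficient is reported both as the mean local value over
    nodes of degree >= 2 and as global transitivity; the diameter is the
    longest shortest path within the largest connected component.
    """
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    m = net.number_of_edges()
    pos, neg = sign_counts(net)
    local = nx.clustering(net)
    eligible = [c for v, c in local.items() if net.degree(v) >= 2]
    mean_local = float(np.mean(eligible)) if eligible else 0.0
    lcc = max(nx.connected_components(net), key=len)
    diam = nx.diameter(net.subgraph(lcc)) if len(lcc) > 1 else 0
    degrees = sorted((d for _, d in net.degree()), reverse=True)
    try:
        r2, slope = powerlaw_r2(degrees)
    except ValueError:
        r2, slope = None, None
    return TopologySummary(
        n_nodes=n,
        n_edges=m,
        n_positive=pos,
        n_negative=neg,
        density=2.0 * m / (n * (n - 1)) if n > 1 else 0.0,
        clustering_mean_local=mean_local,
        clustering_transitivity=float(nx.transitivity(net)),
        diameter_lcc=int(diam),
        degree_sequence=[int(d) for d in degrees],
        powerlaw_r2=r2,
        powerlaw_slope=slope,
    )


def powerlaw_r2(degrees) -> tuple[float, float]:
    """R^2 and slope of the log10 frequency vs log10 degree least-squares line.

    A straight log-log degree-frequency plot is the scale-free signature the
    fit quantifies; degrees k >= 1 with nonzero frequency enter the fit.
    Raises if fewer than 5 distinct such degrees exist.
    """
    degrees = np.asarray(list(degrees), dtype=int)
    ks, freq = np.unique(degrees[degrees >= 1], return_counts=True)
    if ks.size < 5:
        raise ValueError(f"need >= 5 distinct degrees, got {ks.size}")
    res = stats.linregress(np.log10(ks), np.log10(freq))
    return float(res.rvalue**2), float(res.slope)


def powerlaw_mle_exponent(degrees, k_min: int = 1) -> float:
    """Discrete maximum-likelihood power-law exponent (comparison only)."""
    k = np.asarray([d for d in degrees if d >= k_min], dtype=float)
    if k.size == 0:
        raise ValueError("no degrees >= k_min")
    return float(1.0 + k.size / np.log(k / (k_min - 0.5)).sum())


def er_null(n_nodes: int, n_edges: int, seed: int = 0) -> tuple[nx.Graph, dict[int, int]]:
    """Erdos-Renyi G(n, m) null with the same vertex and edge counts.

    Returns the graph and its degree histogram for comparison with the
    observed (power-law-like) degree distribution.
    """
    max_m = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_m:
        raise ValueError(f"m={n_edges} infeasible for n={n_nodes} (max {max_m})")
    g = nx.gnm_random_graph(n_nodes, n_edges, seed=seed)
    hist: dict[int, int] = {}
    for _, d in g.degree():
        hist[d] = hist.get(d, 0) + 1
    return g, dict(sorted(hist.items()))


@dataclass
class NegativeEdgeSummary:
    endpoint_class_counts: dict[str, int]  # {"n-n", "n-e", "e-e"}
    negative_degree: pd.Series  # per gene, descending
    category_counts: pd.Series  # genes with >= 1 negative edge, per category
    subgraph: nx.Graph


def negative_edge_summary(net: nx.Graph) -> NegativeEdgeSummary:
    """Classify negative edges by endpoint prevalence (n = noncore, e = core)."""
    neg_edges = [(a, b) for a, b, d in net.edges(data=True) if d["sign"] == "-"]
    counts = {"n-n": 0, "n-e": 0, "e-e": 0}
    ndeg: dict[str, int] = {}
    for a, b in neg_edges:
        ca = net.nodes[a].get("prevalence")
        cb = net.nodes[b].get("prevalence")
        key = {("core", "core"): "e-e", ("noncore", "noncore"): "n-n"}.get((ca, cb), "n-e")
        counts[key] += 1
        ndeg[a] = ndeg.get(a, 0) + 1
        ndeg[b] = ndeg.get(b, 0) + 1
    series = pd.Series(ndeg, dtype=int, name="negative_degree").sort_values(
        ascending=False, kind="mergesort"
    )
    cats = pd.Series(
        {g: net.nodes[g].get("category", "") for g in ndeg}, name="category"
    ).value_counts()
    sub = net.edge_subgraph(neg_edges).copy() if neg_edges else nx.Graph()
    return NegativeEdgeSummary(counts, series, cats, sub)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test (Mann-Whitney form).

    Exact enumeration when n_x + n_y <= 12 and the pooled sample is tie-free;
    otherwise the normal approximation with tie correction. All-tied input
    returns p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return float(x.size * y.size / 2.0), 1.0
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= 12 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def write_edge_list(net: nx.Graph, path) -> None:
    rows = [
        (a, b, d["sign"], d["weight"], d.get("rho", np.nan))
        for a, b, d in net.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "sign", "weight", "rho"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(net, path)
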