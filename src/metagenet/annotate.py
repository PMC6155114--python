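"""Functional enrichment, DUF function prediction, environment associations.

Guilt-by-association: genes co-clustered in the correlation network tend to
share function, so a cluster's enriched functional categories are candidate
annotations for its unannotated (DUF, "domain of unknown function") members.
Prediction is restricted to DUF genes that are firmly embedded in one
dominant cluster -- several within-cluster edges and none leaving it.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .clusters import Clustering, NodeRole
from .correlation import fdr_adjust
from .data_model import AbundanceTable


def cluster_enrichment(
    clustering: Clustering,
    metadata: pd.DataFrame,
    dominant_ids: list[int],
) -> pd.DataFrame:
    """Hypergeometric category enrichment per dominant cluster, BH-adjusted.

    The universe is the set of network nodes (clustered genes), not all input
    genes; DUF-flagged genes are excluded from both the universe and the
    category counts so predictions cannot leak their own labels. The
    upper-tail p for overlap k is ``P(X >= k)`` with X hypergeometric
    (universe M, category size n, cluster draw N).
    """
    meta = metadata.set_index("gene")
    nodes = [v for v in clustering.membership if v in meta.index and not meta.at[v, "is_duf"]]
    universe = len(nodes)
    cat_of = {v: meta.at[v, "category"] for v in nodes}
    cat_sizes: dict[str, int] = {}
    for c in cat_of.values():
        if c:
            cat_sizes[c] = cat_sizes.get(c, 0) + 1

    rows = []
    for cl in dominant_ids:
        members = [v for v in nodes if clustering.membership[v] == cl]
        size = len(members)
        counts: dict[str, int] = {}
        for v in members:
            c = cat_of[v]
            if c:
                counts[c] = counts.get(c, 0) + 1
        for cat, k in sorted(counts.items()):
            bg = cat_sizes[cat]
            p = float(stats.hypergeom.sf(k - 1, universe, bg, size))
            rows.append({
                "cluster": cl, "category": cat, "overlap": k,
                "cluster_size": size, "category_size": bg, "p": p,
            })
    df = pd.DataFrame(rows, columns=["cluster", "category", "overlap",
                                     "cluster_size", "category_size", "p"])
    df["q"] = fdr_adjust(df["p"].to_numpy()) if len(df) else []
    return df.sort_values(["cluster", "q", "category"], kind="mergesort").reset_index(drop=True)


@dataclass
class DufPrediction:
    gene: str
    cluster: int
    within_degree: int
    between_degree: int
    predicted_categories: list[str]  # ranked ascending by enrichment q
    annotated_neighbors: list[str]


def predict_duf_functions(
    net: nx.Graph,
    clustering: Clustering,
    roles: dict[str, NodeRole],
    enrichment: pd.DataFrame,
    dominant_ids: list[int],
    min_within: int = 3,
    q_max: float = 0.05,
) -> list[DufPrediction]:
    """Predict functions for DUF genes wired strictly inside a dominant cluster.

    Candidates are DUF-flagged nodes with between-cluster degree 0 and
    within-cluster degree >= ``min_within``; the prediction is the ranked
    list of the host cluster's enriched categories (q < ``q_max``), with the
    gene's annotated direct neighbours as supporting evidence.
    """
    dom = set(dominant_ids)
    out: list[DufPrediction] = []
    for v in sorted(net.nodes):
        if not net.nodes[v].get("is_duf", False):
            continue
        cl = clustering.membership[v]
        r = roles[v]
        if cl not in dom or r.between_degree != 0 or r.within_degree < min_within:
            continue
        enr = enrichment[(enrichment["cluster"] == cl) & (enrichment["q"] < q_max)]
        cats = list(enr.sort_values(["q", "category"], kind="mergesort")["category"])
        neighbors = sorted(
            u for u in net.neighbors(v)
            if net.nodes[u].get("category") and not net.nodes[u].get("is_duf", False)
        )
        out.append(DufPrediction(v, cl, r.within_degree, r.between_degree, cats, neighbors))
    return out


def predictions_frame(preds: list[DufPrediction]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "gene": p.gene,
            "cluster": p.cluster,
            "within_degree": p.within_degree,
            "between_degree": p.between_degree,
            "predicted_categories": ";".join(p.predicted_categories),
            "annotated_neighbors": ";".join(p.annotated_neighbors),
        }
        for p in preds
    ], columns=["gene", "cluster", "within_degree", "between_degree",
                "predicted_categories", "annotated_neighbors"])


def env_gene_links(
    env: pd.DataFrame,
    table: AbundanceTable,
    clustering: Clustering | None = None,
    q_max: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Spearman links between environmental factors and gene abundances.

    Every (factor, gene) pair is tested (t-approximation p, BH across all
    pairs). Returns the significant link table, per-factor link counts, and
    -- when a clustering is given -- a per-(factor, cluster) hypergeometric
    concentration test asking whether a factor's linked genes pile up in one
    cluster.
    """
    if list(env.columns) != list(table.samples):
        raise ValueError("environment and abundance tables have mismatched samples")
    n = table.n_samples
    factors = list(env.index)
    if not factors:
        empty = pd.DataFrame(columns=["factor", "gene", "rho", "p", "q"])
        return {"links": empty,
                "factor_counts": pd.DataFrame(columns=["factor", "n_links"]),
                "cluster_concentration": pd.DataFrame(
                    columns=["factor", "cluster", "overlap", "n_linked",
                             "cluster_size", "p", "q"])}

    re_ = stats.rankdata(env.to_numpy(dtype=float), axis=1)
    rg = stats.rankdata(table.values, axis=1)

    def _std(r):
        sd = r.std(axis=1)
        z = np.zeros_like(r)
        ok = sd > 0
        z[ok] = (r[ok] - r[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
        return z

    rho = np.clip(_std(re_) @ _std(rg).T / n, -1.0, 1.0)  # factors x genes
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(p)] = 0.0
    q = fdr_adjust(p.ravel()).reshape(p.shape)

    fi, gi = np.nonzero(q < q_max)
    links = pd.DataFrame({
        "factor": [factors[i] for i in fi],
        "gene": [table.genes[j] for j in gi],
        "rho": rho[fi, gi],
        "p": p[fi, gi],
        "q": q[fi, gi],
    }).sort_values(["factor", "q", "gene"], kind="mergesort").reset_index(drop=True)
    factor_counts = (
        links.groupby("factor").size().reindex(factors, fill_value=0)
        .rename("n_links").reset_index()
    )

    conc_rows = []
    if clustering is not None:
        clustered = [g for g in table.genes if g in clustering.membership]
        M = len(clustered)
        cluster_of = {g: clustering.membership[g] for g in clustered}
        sizes: dict[int, int] = {}
        for c in cluster_of.values():
            sizes[c] = sizes.get(c, 0) + 1
        for f in factors:
            linked = set(links.loc[links["factor"] == f, "gene"]) & set(clustered)
            K = len(linked)
            if K == 0:
                continue
            per_cluster: dict[int, int] = {}
            for g in linked:
                per_cluster[cluster_of[g]] = per_cluster.get(cluster_of[g], 0) + 1
            for c, k in sorted(per_cluster.items()):
                pcl = float(stats.hypergeom.sf(k - 1, M, sizes[c], K))
                conc_rows.append({"factor": f, "cluster": c, "overlap": k,
                                  "n_linked": K, "cluster_size": sizes[c], "p": pcl})
    conc = pd.DataFrame(conc_rows, columns=["factor", "cluster", "overlap",
                                            "n_linked", "cluster_size", "p"])
    conc["q"] = fdr_adjust(conc["p"].to_numpy()) if len(conc) else []
    return {"links": links, "factor_counts": factor_counts, "cluster_concentration": conc}
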