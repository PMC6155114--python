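"""Multi-resolution modularity clustering, hierarchy, hubs and node roles.

Communities are unfolded with the multilevel (Louvain) heuristic on the
positive-edge, unweighted graph. The resolution convention follows the
ecological usage where *larger* resolution values merge communities into
*larger* clusters; internally this maps to the standard modularity
resolution gamma = 1/R (gamma scales the null-model term, and small gamma
favours merging). Sweeping R = 1..15 and linking each cluster to the
cluster holding the plurality of its nodes one level up yields a merge tree
-- the cluster hierarchy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class Clustering:
    resolution: float
    membership: dict[str, int]  # node -> cluster id (0..K-1, by descending size)
    modularity: float
    seed: int

    @property
    def n_clusters(self) -> int:
        return len(set(self.membership.values()))

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in self.membership.values():
            out[c] = out.get(c, 0) + 1
        return dict(sorted(out.items()))

    def members(self, cluster: int) -> list[str]:
        return sorted(v for v, c in self.membership.items() if c == cluster)


def positive_subgraph(net: nx.Graph) -> nx.Graph:
    """Positive-sign edges only; standard modularity is undefined for signed graphs."""
    pos = [(a, b) for a, b, d in net.edges(data=True) if d.get("sign", "+") == "+"]
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from(pos)
    return g


def detect_clusters(net: nx.Graph, resolution: float = 1.0, seed: int = 0) -> Clustering:
    """Louvain communities at one resolution (convention: big R, big clusters)."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    gamma = 1.0 / resolution
    pos = positive_subgraph(net)
    comms = nx.community.louvain_communities(pos, weight=None, resolution=gamma, seed=int(seed))
    comms = sorted(comms, key=lambda c: (-len(c), min(c)))
    membership = {v: i for i, comm in enumerate(comms) for v in comm}
    mod = nx.community.modularity(pos, comms, weight=None, resolution=gamma) \
        if pos.number_of_edges() else 0.0
    return Clustering(float(resolution), membership, float(mod), int(seed))


def multires_scan(
    net: nx.Graph, resolutions=tuple(range(1, 16)), seed: int = 0
) -> list[Clustering]:
    """One clustering per resolution, ascending, with a shared seed policy.

    Cluster counts need not decrease monotonically in R (the heuristic does
    not guarantee it); counts are recorded, not enforced.
    """
    resolutions = list(resolutions)
    if any(b <= a for a, b in zip(resolutions, resolutions[1:])):
        raise ValueError("resolutions must be strictly ascending")
    return [detect_clusters(net, r, seed=seed) for r in resolutions]


def dominant_clusters(
    clustering: Clustering, min_size: int = 10
) -> tuple[list[int], set[str]]:
    """Clusters of size >= min_size; all other nodes become "loose wired"."""
    sizes = clustering.sizes()
    dom = sorted(c for c, s in sizes.items() if s >= min_size)
    dom_set = set(dom)
    loose = {v for v, c in clustering.membership.items() if c not in dom_set}
    return dom, loose


@dataclass
class MergeEvent:
    child_resolution: float
    parent_resolution: float
    parent: int
    children: tuple[int, ...]


@dataclass
class ClusterHierarchy:
    """Merge tree across resolutions built from cluster combination patterns."""

    resolutions: list[float]
    clusterings: list[Clustering]
    # (level index t, cluster at t) -> cluster at t+1
    parent_links: dict[tuple[int, int], int]
    merges: list[MergeEvent] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> dict:
        payload = {
            "resolutions": self.resolutions,
            "parent_links": [
                {"level": t, "cluster": c, "parent": p}
                for (t, c), p in sorted(self.parent_links.items())
            ],
            "merges": [
                {
                    "child_resolution": e.child_resolution,
                    "parent_resolution": e.parent_resolution,
                    "parent": e.parent,
                    "children": list(e.children),
                }
                for e in self.merges
            ],
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
        return payload

    def to_text(self) -> str:
        """Indented tree, top resolution first."""
        lines: list[str] = []
        top = len(self.clusterings) - 1

        children_of: dict[tuple[int, int], list[int]] = {}
        for (t, c), p in self.parent_links.items():
            children_of.setdefault((t + 1, p), []).append(c)

        def walk(level: int, cluster: int, indent: int) -> None:
            size = sum(1 for c in self.clusterings[level].membership.values() if c == cluster)
            lines.append("  " * indent +
                         f"R={self.resolutions[level]:g} cluster {cluster} (n={size})")
            for child in sorted(children_of.get((level, cluster), [])):
                walk(level - 1, child, indent + 1)

        for cluster in sorted(set(self.clusterings[top].membership.values())):
            walk(top, cluster, 0)
        return "\n".join(lines)


def build_hierarchy(clusterings: list[Clustering]) -> ClusterHierarchy:
    """Link each cluster to its plurality container one resolution up.

    The parent of cluster c at level t is the cluster at level t+1 holding
    the most of c's nodes (ties broken by smallest parent id); a merge event
    is recorded whenever >= 2 children share a parent.
    """
    if len(clusterings) < 2:
        raise ValueError("need >= 2 resolution levels")
    for cl in clusterings:
        if not cl.membership:
            raise ValueError(f"empty membership at resolution {cl.resolution}")
    links: dict[tuple[int, int], int] = {}
    merges: list[MergeEvent] = []
    for t in range(len(clusterings) - 1):
        lo, hi = clusterings[t], clusterings[t + 1]
        parents_children: dict[int, list[int]] = {}
        for c in sorted(set(lo.membership.values())):
            votes: dict[int, int] = {}
            for v in lo.membership:
                if lo.membership[v] == c:
                    p = hi.membership[v]
                    votes[p] = votes.get(p, 0) + 1
            best = min(votes, key=lambda p: (-votes[p], p))
            links[(t, c)] = best
            parents_children.setdefault(best, []).append(c)
        for p, kids in sorted(parents_children.items()):
            if len(kids) >= 2:
                merges.append(MergeEvent(lo.resolution, hi.resolution, p, tuple(sorted(kids))))
    return ClusterHierarchy(
        [c.resolution for c in clusterings], list(clusterings), links, merges
    )


def inter_cluster_connectivity(net: nx.Graph, clustering: Clustering) -> pd.DataFrame:
    """Cluster x cluster edge-count matrix; diagonal = within-cluster counts.

    Upper triangle + diagonal sums to the network's edge count.
    """
    ids = sorted(set(clustering.membership.values()))
    idx = {c: i for i, c in enumerate(ids)}
    m = np.zeros((len(ids), len(ids)), dtype=int)
    for a, b in net.edges:
        ca, cb = clustering.membership[a], clustering.membership[b]
        i, j = idx[ca], idx[cb]
        if i == j:
            m[i, i] += 1
        else:
            m[i, j] += 1
            m[j, i] += 1
    return pd.DataFrame(m, index=ids, columns=ids)


@dataclass(frozen=True)
class NodeRole:
    within_degree: int
    between_degree: int
    is_hub: bool
    role: str  # "intra" (no between-cluster edges) or "inter"


def node_roles(
    net: nx.Graph, clustering: Clustering, hubs: dict[int, str] | None = None
) -> dict[str, NodeRole]:
    """Within/between-cluster degree split and the intra/inter role.

    kw + kb equals total degree for every node; role is "intra" iff kb = 0.
    """
    hub_genes = set((hubs or {}).values())
    roles: dict[str, NodeRole] = {}
    for v in net.nodes:
        kw = kb = 0
        cv = clustering.membership[v]
        for u in net.neighbors(v):
            if clustering.membership[u] == cv:
                kw += 1
            else:
                kb += 1
        roles[v] = NodeRole(kw, kb, v in hub_genes, "intra" if kb == 0 else "inter")
    return roles


def cluster_hubs(
    net: nx.Graph, clustering: Clustering, dominant_ids: list[int]
) -> tuple[dict[int, str], pd.DataFrame]:
    """One hub per dominant cluster: the member with the highest total degree.

    Ties break by larger within-cluster degree, then lexicographic id. The
    table reports degree, kw, kb, role and node attributes per hub.
    """
    if not dominant_ids:
        raise ValueError("empty dominant cluster set")
    hubs: dict[int, str] = {}
    for c in dominant_ids:
        members = [v for v, cc in clustering.membership.items() if cc == c]
        if not members:
            raise ValueError(f"dominant cluster {c} has no members")

        def key(v: str):
            deg = net.degree(v)
            kw = sum(1 for u in net.neighbors(v) if clustering.membership[u] == c)
            return (-deg, -kw, v)

        hubs[c] = min(members, key=key)
    rows = []
    for c, v in sorted(hubs.items()):
        kw = sum(1 for u in net.neighbors(v) if clustering.membership[u] == c)
        kb = net.degree(v) - kw
        rows.append({
            "cluster": c,
            "gene": v,
            "degree": net.degree(v),
            "within_degree": kw,
            "between_degree": kb,
            "role": "intra" if kb == 0 else "inter",
            "prevalence": net.nodes[v].get("prevalence", ""),
            "is_duf": bool(net.nodes[v].get("is_duf", False)),
            "category": net.nodes[v].get("category", ""),
        })
    return hubs, pd.DataFrame(rows)


def membership_frame(clusterings: list[Clustering]) -> pd.DataFrame:
    """Long-format membership table: gene, resolution, cluster."""
    rows = [
        (v, cl.resolution, c)
        for cl in clusterings
        for v, c in sorted(cl.membership.items())
    ]
    return pd.DataFrame(rows, columns=["gene", "resolution", "cluster"])
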