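"""Synthetic abundance tables with planted, fully known correlation structure.

The generator emulates the statistical shape of a multi-site metagenome gene
abundance survey (default 45 samples) so that every downstream stage of the
network pipeline can be checked against ground truth:

* K latent cluster factors, i.i.d. standard normal across samples;
* each cluster gene g is ``w_g * f_k + sqrt(1 - w_g^2) * eps`` with one
  high-loading hub per cluster (``hub_loading``) and ``member_loading`` for
  the rest, so the planted rank correlation between genes i, j is ``w_i w_j``;
* abundances are ``exp()`` of the latent values -- a strictly increasing
  positive map, so planted Spearman correlations are exact by construction;
* a core / non-core / excluded prevalence structure imposed by zeroing
  (zero = not detected) after the transform;
* optionally: anti-correlated cluster pairs (negative latent coupling),
  sibling clusters nested under shared parent factors, and environmental
  factors coupled to specific cluster factors.

The model is a stand-in for real survey noise, not an inference from any
data set; what it does and does not emulate is discussed in the methods note.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import stage_rng
from .data_model import AbundanceTable

# Latent coupling used for anti-correlated factor pairs; yields empirical
# correlation ~ -0.98 at n = 45 (contract: <= -0.9).
_NEG_COUPLING = 0.98


@dataclass
class SyntheticSpec:
    """Parameters of the planted-structure generator.

    Defaults mirror a 45-sample survey design with a small number of clusters
    (large-K presets are available via :meth:`survey_scale`).
    """

    n_samples: int = 45
    n_clusters: int = 6
    genes_per_cluster: int = 20
    hub_loading: float = 0.95
    member_loading: float = 0.8
    n_background_genes: int = 40
    frac_core: float = 0.6
    noncore_presence_range: tuple[int, int] = (25, 44)
    n_excluded_genes: int = 10
    negative_pairs: tuple[tuple[int, int], ...] = ()
    nested_parents: dict[int, tuple[int, ...]] | None = None
    parent_loading: float = 0.8
    env_factors: int = 0
    env_coupling: dict[int, int] = field(default_factory=dict)
    env_noise_sd: float = 0.3
    noise_sd: float = 1.0
    duf_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if self.genes_per_cluster < 1:
            raise ValueError("genes_per_cluster must be >= 1")
        for name in ("hub_loading", "member_loading"):
            w = getattr(self, name)
            if not 0.0 < w <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {w}")
        if self.nested_parents is not None:
            if not 0.0 < self.parent_loading < 1.0:
                raise ValueError("parent_loading must lie in (0, 1)")
            children = [c for kids in self.nested_parents.values() for c in kids]
            if len(set(children)) != len(children):
                raise ValueError("a cluster may have at most one parent")
            bad = [c for c in children if not 0 <= c < self.n_clusters]
            if bad:
                raise ValueError(f"nested_parents references unknown clusters {bad}")
        lo, hi = self.noncore_presence_range
        if not (0 <= lo <= hi <= self.n_samples):
            raise ValueError(
                f"noncore_presence_range {self.noncore_presence_range} outside [0, {self.n_samples}]"
            )
        for a, b in self.negative_pairs:
            if not (0 <= a < self.n_clusters and 0 <= b < self.n_clusters) or a == b:
                raise ValueError(f"invalid negative pair ({a}, {b})")
        nested = set() if self.nested_parents is None else {
            c for kids in self.nested_parents.values() for c in kids
        }
        overlap = nested & {c for pair in self.negative_pairs for c in pair}
        if overlap:
            raise ValueError(f"clusters {sorted(overlap)} cannot be both nested and negatively paired")
        for f, c in self.env_coupling.items():
            if not 0 <= f < self.env_factors:
                raise ValueError(f"env_coupling references unknown env factor {f}")
            if not 0 <= c < self.n_clusters:
                raise ValueError(f"env_coupling references unknown cluster {c}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.duf_fraction < 1.0:
            raise ValueError("duf_fraction must lie in [0, 1)")
        if not 0.0 <= self.frac_core <= 1.0:
            raise ValueError("frac_core must lie in [0, 1]")

    @classmethod
    def survey_scale(cls, seed: int = 0) -> "SyntheticSpec":
        """A 27-cluster, 45-sample preset mirroring a large field survey."""
        return cls(n_clusters=27, genes_per_cluster=15, n_background_genes=60,
                   n_excluded_genes=20, seed=seed)


@dataclass
class GroundTruth:
    """Planted structure of a generated data set."""

    gene_cluster: dict[str, int | None]
    hubs: dict[int, str]
    cluster_labels: dict[int, str]
    prevalence_class: dict[str, str]
    presence: dict[str, int]
    negative_pairs: tuple[tuple[int, int], ...]
    parent_of: dict[int, int]
    env_coupling: dict[int, int]
    duf_genes: dict[str, str] = field(default_factory=dict)  # gene -> withheld category

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gene_cluster": self.gene_cluster,
            "hubs": {str(k): v for k, v in self.hubs.items()},
            "cluster_labels": {str(k): v for k, v in self.cluster_labels.items()},
            "prevalence_class": self.prevalence_class,
            "presence": self.presence,
            "negative_pairs": [list(p) for p in self.negative_pairs],
            "parent_of": {str(k): v for k, v in self.parent_of.items()},
            "env_coupling": {str(k): v for k, v in self.env_coupling.items()},
            "duf_genes": self.duf_genes,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def generate_latent_factors(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw the cluster factor matrix, rows = factors, columns = samples.

    Rows 0..K-1 are cluster factors; parent factors (if any) are appended
    after them. Independent clusters get i.i.d. standard normal rows; nested
    children share variance with their parent at ``parent_loading**2``;
    negatively paired clusters get anti-correlated rows (corr <= -0.9).
    """
    spec.validate()
    if rng is None:
        rng = stage_rng(spec.seed, "simulate")
    K, n = spec.n_clusters, spec.n_samples
    parents = spec.nested_parents or {}
    parent_ids = sorted(parents)
    F = rng.standard_normal((K + len(parent_ids), n))
    for pi, pid in enumerate(parent_ids):
        fp = F[K + pi]
        w = spec.parent_loading
        for child in parents[pid]:
            F[child] = w * fp + np.sqrt(1 - w * w) * rng.standard_normal(n)
    for a, b in spec.negative_pairs:
        c = _NEG_COUPLING
        F[b] = -(c * F[a] + np.sqrt(1 - c * c) * rng.standard_normal(n))
    return F


def generate_abundance(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[AbundanceTable, GroundTruth, np.ndarray]:
    """Generate the abundance table, its ground truth, and the factor matrix."""
    spec.validate()
    if rng is None:
        rng = stage_rng(spec.seed, "simulate")
    F = generate_latent_factors(spec, rng)
    K, n = spec.n_clusters, spec.n_samples
    min_prev = spec.noncore_presence_range[0]

    genes: list[str] = []
    latent_rows: list[np.ndarray] = []
    gene_cluster: dict[str, int | None] = {}
    hubs: dict[int, str] = {}

    for k in range(K):
        for i in range(spec.genes_per_cluster):
            gid = f"g{k:02d}_{i:03d}"
            w = spec.hub_loading if i == 0 else spec.member_loading
            eps = spec.noise_sd * rng.standard_normal(n)
            latent_rows.append(w * F[k] + np.sqrt(1 - w * w) * eps)
            genes.append(gid)
            gene_cluster[gid] = k
            if i == 0:
                hubs[k] = gid
    for i in range(spec.n_background_genes):
        gid = f"bg_{i:03d}"
        latent_rows.append(spec.noise_sd * rng.standard_normal(n))
        genes.append(gid)
        gene_cluster[gid] = None
    for i in range(spec.n_excluded_genes):
        gid = f"ex_{i:03d}"
        latent_rows.append(spec.noise_sd * rng.standard_normal(n))
        genes.append(gid)
        gene_cluster[gid] = None

    # Strictly increasing positive map: preserves within-gene ranks exactly.
    values = np.exp(np.vstack(latent_rows))

    prevalence_class: dict[str, str] = {}
    presence: dict[str, int] = {}
    n_regular = K * spec.genes_per_cluster + spec.n_background_genes
    for row, gid in enumerate(genes):
        if row >= n_regular:  # planted below-threshold gene
            pres = int(rng.integers(1, max(min_prev, 2)))
            label = "excluded"
        elif rng.random() < spec.frac_core:
            pres, label = n, "core"
        else:
            lo, hi = spec.noncore_presence_range
            pres = int(rng.integers(lo, hi + 1))
            label = "noncore" if pres < n else "core"
        if pres > n:
            raise ValueError(f"requested presence {pres} exceeds n_samples {n}")
        if pres < n:
            absent = rng.choice(n, size=n - pres, replace=False)
            values[row, absent] = 0.0
        prevalence_class[gid] = label
        presence[gid] = pres

    table = AbundanceTable(genes, [f"S{j + 1:02d}" for j in range(n)], values)
    truth = GroundTruth(
        gene_cluster=gene_cluster,
        hubs=hubs,
        cluster_labels={k: f"fam{k:02d}" for k in range(K)},
        prevalence_class=prevalence_class,
        presence=presence,
        negative_pairs=tuple(spec.negative_pairs),
        parent_of={c: p for p, kids in (spec.nested_parents or {}).items() for c in kids},
        env_coupling=dict(spec.env_coupling),
    )
    return table, truth, F


def generate_metadata(
    spec: SyntheticSpec, truth: GroundTruth, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Assign functional-category labels; withhold a DUF fraction per cluster.

    Each planted cluster gets a distinct label applied to its members;
    ``floor(duf_fraction * genes_per_cluster)`` non-hub members per cluster are
    flagged DUF with an empty category (the withheld label is kept in
    ``truth.duf_genes``). Background and excluded genes share a "background"
    label.
    """
    if rng is None:
        rng = stage_rng(spec.seed, "metadata")
    n_duf = int(spec.duf_fraction * spec.genes_per_cluster)
    duf: dict[str, str] = {}
    by_cluster: dict[int, list[str]] = {}
    for g, k in truth.gene_cluster.items():
        if k is not None:
            by_cluster.setdefault(k, []).append(g)
    for k, members in sorted(by_cluster.items()):
        candidates = sorted(g for g in members if g != truth.hubs[k])
        chosen = rng.choice(len(candidates), size=min(n_duf, len(candidates)), replace=False)
        for ci in sorted(chosen):
            duf[candidates[ci]] = truth.cluster_labels[k]
    truth.duf_genes = duf

    rows = []
    for g, k in truth.gene_cluster.items():
        if g in duf:
            rows.append((g, "", True))
        elif k is None:
            rows.append((g, "background", False))
        else:
            rows.append((g, truth.cluster_labels[k], False))
    return pd.DataFrame(rows, columns=["gene", "category", "is_duf"])


def generate_env(
    spec: SyntheticSpec, factors: np.ndarray, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Environmental factor table (factors x samples).

    Coupled factors are their target cluster factor plus noise at
    ``env_noise_sd``; uncoupled factors are i.i.d. standard normal.
    """
    if rng is None:
        rng = stage_rng(spec.seed, "env")
    n = spec.n_samples
    samples = [f"S{j + 1:02d}" for j in range(n)]
    rows = []
    for f in range(spec.env_factors):
        if f in spec.env_coupling:
            row = factors[spec.env_coupling[f]] + spec.env_noise_sd * rng.standard_normal(n)
        else:
            row = rng.standard_normal(n)
        rows.append(row)
    values = np.vstack(rows) if rows else np.empty((0, n))
    return pd.DataFrame(values, index=[f"env{f:02d}" for f in range(spec.env_factors)],
                        columns=samples)


@dataclass
class SyntheticDataset:
    abundance: AbundanceTable
    metadata: pd.DataFrame
    env: pd.DataFrame
    truth: GroundTruth
    factors: np.ndarray


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate all tables of one synthetic study in a single seeded run."""
    table, truth, F = generate_abundance(spec)
    meta = generate_metadata(spec, truth)
    env = generate_env(spec, F)
    return SyntheticDataset(table, meta, env, truth, F)


def nested_partition_graph(
    n_parents: int = 2,
    siblings_per_parent: int = 2,
    nodes_per_sibling: int = 25,
    p_in: float = 0.9,
    p_sibling: float = 0.08,
    p_parent: float = 0.0,
    seed: int = 0,
):
    """A planted nested-community graph: siblings dense, parents sparse.

    The direct network-level counterpart of ``nested_parents``: sibling
    clusters under one parent are joined with probability ``p_sibling``
    (``p_parent`` across parents, default 0), so a multi-resolution sweep
    should resolve siblings at resolution 1 and merge them into their parent
    at coarser resolutions. Returns ``(graph, sibling_of, parent_of)`` where
    the maps give each node's planted sibling cluster and parent. Edges carry
    ``sign='+'`` so the graph plugs into the clustering stage directly.
    """
    import networkx as nx

    rng = np.random.default_rng(seed)
    g = nx.Graph()
    sibling_of: dict[str, int] = {}
    parent_of: dict[int, int] = {}
    nodes_by_sibling: dict[int, list[str]] = {}
    sib = 0
    for parent in range(n_parents):
        for _ in range(siblings_per_parent):
            names = [f"v{sib:02d}_{i:03d}" for i in range(nodes_per_sibling)]
            g.add_nodes_from(names)
            nodes_by_sibling[sib] = names
            parent_of[sib] = parent
            for v in names:
                sibling_of[v] = sib
            sib += 1
    sibs = sorted(nodes_by_sibling)
    for a in sibs:
        na = nodes_by_sibling[a]
        for i in range(len(na)):
            for j in range(i + 1, len(na)):
                if rng.random() < p_in:
                    g.add_edge(na[i], na[j], sign="+")
        for b in sibs:
            if b <= a:
                continue
            p = p_sibling if parent_of[a] == parent_of[b] else p_parent
            if p <= 0:
                continue
            for u in na:
                for v in nodes_by_sibling[b]:
                    if rng.random() < p:
                        g.add_edge(u, v, sign="+")
    return g, sibling_of, parent_of


def planted_block_matrix(
    n_blocks: int = 4,
    block_size: int = 40,
    within_range: tuple[float, float] = (0.85, 0.95),
    between_base: float = 0.30,
    between_jitter: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """A synthetic "correlation-like" matrix with modular blocks.

    Within-block entries are uniform in ``within_range``; between-block
    entries are ``between_base`` +/- ``between_jitter`` (dense noise band).
    Used to exercise threshold selection: below the noise band the matrix is
    one dense random matrix (GOE-like spectra); above it, independent blocks
    (Poisson-like spacings).
    """
    rng = np.random.default_rng(seed)
    n = n_blocks * block_size
    lo = max(0.0, between_base - between_jitter)
    hi = between_base + between_jitter
    m = rng.uniform(lo, hi, size=(n, n))
    for b in range(n_blocks):
        s = slice(b * block_size, (b + 1) * block_size)
        m[s, s] = rng.uniform(*within_range, size=(block_size, block_size))
    m = np.triu(m, 1)
    m = m + m.T
    np.fill_diagonal(m, 1.0)
    return m
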