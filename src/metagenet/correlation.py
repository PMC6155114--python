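"""Spearman correlation matrices, FDR adjustment, and network deconvolution.

Deconvolution treats the observed association matrix as the transitive
closure of a direct-dependency matrix, ``G_obs = G_dir + G_dir^2 + ...``,
and inverts that series on the eigenvalues: if ``G_obs = U diag(l) U^T``
then the direct part is ``U diag(l / (1 + l)) U^T``. A global scaling
``gamma`` keeps the output spectrum inside ``(-beta, beta)`` so the series
converges; with ``alpha < 1`` only the strongest ``alpha`` fraction of
entries is deconvolved.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import check_symmetric


@dataclass
class DeconvolutionParams:
    """alpha = fraction of strongest entries retained; beta = spectral bound."""

    alpha: float = 1.0
    beta: float = 0.99

    def validate(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")
        if not 0.0 < self.beta < 1.0:
            raise ValueError(f"beta must lie in (0, 1), got {self.beta}")


@dataclass
class CorrelationResult:
    """Pairwise Spearman statistics for one gene set.

    ``rho``, ``p`` and ``q`` are symmetric genes x genes matrices;
    ``deconvolved_rho`` (zero diagonal) holds direct-dependency scores once
    :func:`deconvolve` has run.
    """

    genes: list[str]
    rho: np.ndarray
    p: np.ndarray
    q: np.ndarray | None = None
    deconvolved_rho: np.ndarray | None = None
    constant_genes: list[str] = field(default_factory=list)

    def to_long(self) -> pd.DataFrame:
        """Upper-triangle long format: gene_a, gene_b, rho, p, q."""
        iu = np.triu_indices(len(self.genes), k=1)
        data = {
            "gene_a": [self.genes[i] for i in iu[0]],
            "gene_b": [self.genes[j] for j in iu[1]],
            "rho": self.rho[iu],
            "p": self.p[iu],
        }
        if self.q is not None:
            data["q"] = self.q[iu]
        if self.deconvolved_rho is not None:
            data["deconvolved_rho"] = self.deconvolved_rho[iu]
        return pd.DataFrame(data)


def spearman_matrix(table, method: str = "t") -> CorrelationResult:
    """All-pairs Spearman rho with two-sided p-values and BH q-values.

    rho is the Pearson correlation of average-ranked values (average ranks on
    ties). ``method='t'`` uses the t approximation
    ``t = rho * sqrt((n-2) / (1-rho^2))`` on n-2 df, adequate for n around
    45; ``method='exact'`` enumerates rank permutations (only feasible for
    n < 10). Constant genes get rho = 0, p = 1 against every partner.
    """
    X = np.asarray(table.values, dtype=float)
    genes = list(table.genes)
    n = X.shape[1]
    if n < 4:
        raise ValueError(f"need >= 4 samples, got {n}")

    R = stats.rankdata(X, axis=1)
    sd = R.std(axis=1)
    const = sd == 0
    Z = np.zeros_like(R)
    ok = ~const
    Z[ok] = (R[ok] - R[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
    rho = np.clip(Z @ Z.T / n, -1.0, 1.0)
    rho[const, :] = 0.0
    rho[:, const] = 0.0
    np.fill_diagonal(rho, 1.0)

    if method == "t":
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        p[np.isnan(p)] = 0.0  # |rho| == 1 -> t = inf -> p = 0
    elif method == "exact":
        p = np.ones_like(rho)
        for i, j in itertools.combinations(range(len(genes)), 2):
            p[i, j] = p[j, i] = spearman_exact_p(X[i], X[j])
    else:
        raise ValueError(f"unknown method {method!r}")
    p = np.clip(p, 0.0, 1.0)
    p[const, :] = 1.0
    p[:, const] = 1.0
    np.fill_diagonal(p, 0.0)

    q = fdr_adjust_matrix(p)
    return CorrelationResult(
        genes=genes, rho=rho, p=p, q=q,
        constant_genes=[g for g, c in zip(genes, const) if c],
    )


def spearman_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided permutation p-value for Spearman rho (n < 10 only)."""
    n = len(x)
    if n >= 10:
        raise ValueError("exact permutation p-value is limited to n < 10")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(_rank_corr(rx, ry))
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(_rank_corr(rx, np.asarray(perm))) >= obs - 1e-12:
            count += 1
    return count / total


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))


def fdr_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("fdr_adjust expects a 1-d array of p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fdr_adjust_matrix(p: np.ndarray) -> np.ndarray:
    """BH over the upper triangle (one hypothesis per gene pair); symmetric."""
    p = check_symmetric(p, "p matrix")
    iu = np.triu_indices(p.shape[0], k=1)
    q_flat = fdr_adjust(p[iu])
    q = np.zeros_like(p)
    q[iu] = q_flat
    q = q + q.T
    return q


def deconvolve(
    rho: np.ndarray,
    params: DeconvolutionParams | None = None,
    gamma: float | None = None,
    zero_diagonal: bool = True,
) -> np.ndarray:
    """Suppress indirect (transitive) associations by spectral inversion.

    Steps: optionally keep only the strongest ``alpha`` fraction of
    off-diagonal entries; eigendecompose; map each eigenvalue l to
    ``gamma l / (1 + gamma l)`` with ``gamma`` chosen in closed form so the
    output spectral radius is exactly ``beta`` (gamma = 1 if the input is
    already within bound); reconstruct and re-symmetrize.

    ``gamma`` may be forced (e.g. to 1) to realise the exact inverse of the
    transitive-closure map; ``zero_diagonal=False`` likewise skips the
    diagonal clearing so closure round-trips are exact.
    """
    if params is None:
        params = DeconvolutionParams()
    params.validate()
    G = check_symmetric(rho, "rho").copy()
    if zero_diagonal:
        np.fill_diagonal(G, 0.0)
    if params.alpha < 1.0:
        iu = np.triu_indices(G.shape[0], k=1)
        mags = np.abs(G[iu])
        k = int(np.ceil(params.alpha * mags.size))
        if k < mags.size:
            cut = np.partition(mags, mags.size - k)[mags.size - k]
            mask = np.abs(G) < cut
            np.fill_diagonal(mask, False)
            G[mask] = 0.0
    G = (G + G.T) / 2.0

    lam, U = np.linalg.eigh(G)
    if gamma is None:
        beta = params.beta
        cands = [1.0]
        lmax, lmin = lam.max(), lam.min()
        if lmax > 0:
            cands.append(beta / ((1.0 - beta) * lmax))
        if lmin < 0:
            cands.append(beta / ((1.0 + beta) * (-lmin)))
        gamma = min(cands)
    lam_d = gamma * lam / (1.0 + gamma * lam)
    out = (U * lam_d) @ U.T
    out = (out + out.T) / 2.0
    if zero_diagonal:
        np.fill_diagonal(out, 0.0)
    return out


def transitive_closure(direct: np.ndarray) -> np.ndarray:
    """Forward map ``D -> U diag(l / (1 - l)) U^T`` (spectral radius < 1).

    The exact inverse of :func:`deconvolve` with ``gamma=1`` and
    ``zero_diagonal=False``; used as an independent oracle.
    """
    D = check_symmetric(direct, "direct")
    lam, U = np.linalg.eigh(D)
    if np.abs(lam).max() >= 1.0:
        raise ValueError("spectral radius must be < 1 for the closure series to converge")
    return (U * (lam / (1.0 - lam))) @ U.T
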