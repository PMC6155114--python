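"""Random-matrix-theory threshold selection.

The similarity threshold for network construction is chosen automatically by
scanning candidate cutoffs and watching the nearest-neighbour spacing
distribution (NNSD) of the thresholded matrix's eigenvalues. A dense,
noise-coupled matrix behaves like a Gaussian orthogonal ensemble (GOE)
matrix -- unfolded spacings follow the Wigner surmise
``P(s) = (pi s / 2) exp(-pi s^2 / 4)`` (level repulsion). Once the cutoff
removes the noise band, the matrix decomposes into quasi-independent modules
whose superposed spectra have uncorrelated levels -- spacings follow the
Poisson law ``P(s) = exp(-s)``. The chosen threshold is the smallest cutoff
at which the NNSD is (and stably remains) consistent with Poisson.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline

from ._util import check_symmetric

DEFAULT_GRID = np.round(np.arange(0.30, 0.991, 0.01), 2)


class ThresholdNotFoundError(RuntimeError):
    pass


def unfolded_spacings(
    matrix: np.ndarray,
    min_eigen: int = 100,
    seed: int = 0,
    smoothing: float | None = None,
) -> np.ndarray:
    """Eigenvalue spacings after spectral unfolding, normalised to mean 1.

    Unfolding rescales the spectrum so its local mean spacing is 1
    everywhere, which makes NNSDs of different matrices comparable: a cubic
    smoothing spline is fit to the empirical cumulative spectral density and
    evaluated at the (sorted) eigenvalues. Exact duplicate eigenvalues are
    perturbed by a seeded jitter <= 1e-12 so the fit abscissae are strictly
    increasing. The smoothing parameter defaults to ``n**-0.5``.
    """
    m = check_symmetric(matrix, "matrix")
    n = m.shape[0]
    if n < min_eigen:
        raise ValueError(f"matrix dimension {n} below min_eigen {min_eigen}")
    lam = np.sort(np.linalg.eigvalsh(m))
    dup = np.flatnonzero(np.diff(lam) <= 0)
    if dup.size:
        rng = np.random.default_rng(seed)
        jitter = np.sort(rng.uniform(0.0, 1e-12, size=n))
        lam = np.sort(lam + jitter)
        # guarantee strict monotonicity even after jitter
        for i in range(1, n):
            if lam[i] <= lam[i - 1]:
                lam[i] = lam[i - 1] + 1e-15
    F = (np.arange(1, n + 1) - 0.5) / n
    s = n ** -0.5 if smoothing is None else smoothing
    with warnings.catch_warnings():
        # FITPACK grumbles when the smoothing target is not met exactly; the
        # returned approximation is still a valid unfolding curve.
        warnings.simplefilter("ignore", UserWarning)
        spline = UnivariateSpline(lam, F, k=3, s=s)
    unfolded = n * np.maximum.accumulate(spline(lam))
    spacings = np.diff(unfolded)
    spacings = spacings[spacings > 0]
    if spacings.size == 0:
        raise ValueError("degenerate spectrum: no positive unfolded spacings")
    return spacings / spacings.mean()


def _law_cdf(s: np.ndarray, law: str) -> np.ndarray:
    if law == "poisson":
        return 1.0 - np.exp(-s)
    if law == "goe":
        return 1.0 - np.exp(-np.pi * s**2 / 4.0)
    raise ValueError(f"unknown law {law!r} (expected 'poisson' or 'goe')")


def nnsd_chisq(
    spacings: np.ndarray, law: str, n_bins: int = 30, s_max: float = 3.0
) -> tuple[float, int]:
    """Goodness-of-fit chi^2 of the NNSD against a reference spacing law.

    Spacings are histogrammed into ``n_bins`` equal bins on ``[0, s_max]``
    with overflow pooled into the last bin; expected counts integrate the
    named law's density per bin (last bin takes the tail mass). Bins with
    expected count < 1 are merged into their left neighbour. Returns
    (chi2, dof) with dof = used_bins - 1.
    """
    spacings = np.asarray(spacings, dtype=float)
    if spacings.size < 30:
        raise ValueError(f"need >= 30 spacings, got {spacings.size}")
    edges = np.linspace(0.0, s_max, n_bins + 1)
    obs, _ = np.histogram(np.minimum(spacings, s_max - 1e-12), bins=edges)
    cdf = _law_cdf(edges, law)
    exp = np.diff(cdf) * spacings.size
    exp[-1] += (1.0 - cdf[-1]) * spacings.size  # tail mass into overflow bin

    obs_m: list[float] = []
    exp_m: list[float] = []
    for o, e in zip(obs, exp):
        if exp_m and exp_m[-1] < 1.0:
            obs_m[-1] += o
            exp_m[-1] += e
        else:
            obs_m.append(float(o))
            exp_m.append(float(e))
    # a trailing underfull bin merges left
    while len(exp_m) > 1 and exp_m[-1] < 1.0:
        exp_m[-2] += exp_m.pop()
        obs_m[-2] += obs_m.pop()
    obs_a, exp_a = np.array(obs_m), np.array(exp_m)
    chi2 = float(((obs_a - exp_a) ** 2 / exp_a).sum())
    return chi2, len(exp_a) - 1


@dataclass
class RmtScan:
    """Record of a threshold scan and the chosen cutoff."""

    grid: np.ndarray
    retained_size: np.ndarray
    chi2_poisson: np.ndarray  # NaN where not evaluable
    chi2_goe: np.ndarray
    dof: np.ndarray
    poisson_ok: np.ndarray  # bool; False where not evaluable
    chosen_threshold: float
    test_alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.grid,
            "retained_size": self.retained_size,
            "chi2_poisson": self.chi2_poisson,
            "chi2_goe": self.chi2_goe,
            "dof": self.dof,
            "poisson_ok": self.poisson_ok,
            "chosen": np.isclose(self.grid, self.chosen_threshold),
        })


def scan_threshold(
    matrix: np.ndarray,
    grid: np.ndarray | None = None,
    min_eigen: int = 100,
    test_alpha: float = 0.001,
    seed: int = 0,
    stability_window: int = 5,
) -> RmtScan:
    """Scan cutoffs; choose the smallest stably-Poisson threshold.

    For each cutoff ``s`` the matrix ``A_ij = |m_ij|`` where ``|m_ij| >= s``
    (else 0, diagonal 0) is formed and all-zero rows/columns dropped. Where
    the retained dimension allows it, the NNSD chi^2 against the Poisson law
    is computed; a threshold "passes" if chi2 falls below the chi^2 critical
    value at ``test_alpha``. The chosen threshold is the smallest grid point
    that passes and whose next ``stability_window`` evaluable successors all
    pass too; the windowed rule keeps the choice at the Poisson transition
    while ignoring spurious flickers at the top of the grid, where the
    retained matrix is nearly degenerate and the spacing law breaks down for
    reasons unrelated to the transition.
    """
    m = check_symmetric(matrix, "matrix")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be non-empty and strictly ascending")
    absm = np.abs(m).copy()
    np.fill_diagonal(absm, 0.0)

    sizes = np.zeros(grid.size, dtype=int)
    chi_p = np.full(grid.size, np.nan)
    chi_g = np.full(grid.size, np.nan)
    dofs = np.zeros(grid.size, dtype=int)
    ok = np.zeros(grid.size, dtype=bool)
    any_edges = False
    for gi, s in enumerate(grid):
        A = np.where(absm >= s, absm, 0.0)
        keep = A.any(axis=0)
        size = int(keep.sum())
        sizes[gi] = size
        if size == 0:
            continue
        any_edges = True
        if size < max(min_eigen, 31):
            continue
        try:
            sp = unfolded_spacings(A[np.ix_(keep, keep)], min_eigen=0, seed=seed)
        except ValueError:  # fully degenerate spectrum at this cutoff
            continue
        if sp.size < 30:
            continue
        chi_p[gi], dof = nnsd_chisq(sp, "poisson")
        chi_g[gi], _ = nnsd_chisq(sp, "goe")
        dofs[gi] = dof
        crit = stats.chi2.ppf(1.0 - test_alpha, dof)
        ok[gi] = chi_p[gi] < crit

    if not any_edges:
        raise ThresholdNotFoundError("no edges at any threshold")
    evaluable = ~np.isnan(chi_p)
    chosen = None
    eval_idx = np.flatnonzero(evaluable)
    for pos, gi in enumerate(eval_idx):
        if not ok[gi]:
            continue
        successors = eval_idx[pos + 1: pos + 1 + stability_window]
        if np.all(ok[successors]):
            chosen = float(grid[gi])
            break
    if chosen is None:
        if not evaluable.any():
            raise ThresholdNotFoundError(
                f"retained matrix smaller than min_eigen={min_eigen} at every threshold"
            )
        raise ThresholdNotFoundError(
            "no threshold satisfies the stable-Poisson criterion"
        )
    return RmtScan(grid, sizes, chi_p, chi_g, dofs, ok, chosen, test_alpha)
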