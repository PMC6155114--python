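"""Input tables and prevalence classification.

The pipeline's sole biological input is a genes x samples abundance table of
non-negative values. Genes are classified by *prevalence* -- the number of
samples in which they are detected (abundance > 0):

* ``core``      detected in every sample,
* ``noncore``   detected in at least ``min_prevalence`` but not all samples,
* ``excluded``  detected in fewer than ``min_prevalence`` samples; dropped
  before correlation, because rank correlations on very sparse rows are
  dominated by shared zeros.

The default ``min_prevalence=25`` matches a 45-sample study design (25 of 45);
both numbers are parameters here, with ``n_samples`` read from the table.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd


class Prevalence(str, Enum):
    CORE = "core"
    NONCORE = "noncore"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class PrevalenceClass:
    label: Prevalence
    presence: int


@dataclass
class AbundanceTable:
    """Genes x samples non-negative matrix with unique string ids."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray  # shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        _check_unique(self.genes, "gene")
        _check_unique(self.samples, "sample")
        if np.isnan(self.values).any():
            g, s = np.argwhere(np.isnan(self.values))[0]
            raise ValueError(f"missing value at gene {self.genes[g]!r}, sample {self.samples[s]!r}")
        if (self.values < 0).any():
            g, s = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative value {self.values[g, s]!r} at gene {self.genes[g]!r}, "
                f"sample {self.samples[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AbundanceTable":
        return cls(list(map(str, df.index)), list(map(str, df.columns)), df.to_numpy(dtype=float))

    def subset(self, genes: list[str]) -> "AbundanceTable":
        idx = {g: i for i, g in enumerate(self.genes)}
        rows = [idx[g] for g in genes]
        return AbundanceTable(list(genes), list(self.samples), self.values[rows])


def _check_unique(ids: list[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {kind} id {i!r}")
        seen.add(i)


# ---------------------------------------------------------------- I/O (TSV)
# Dialect: tab-separated, UTF-8, '.' decimal, first column is the id, header
# row holds sample ids, no quoting.


def read_abundance(path: str | Path) -> AbundanceTable:
    df = _read_tsv(path)
    return AbundanceTable.from_frame(df)


def write_abundance(table: AbundanceTable, path: str | Path) -> None:
    _write_tsv(table.to_frame(), path, index_label="gene")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Gene metadata: columns ``gene``, ``category``, ``is_duf``."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "category": str})
    for col in ("gene", "category", "is_duf"):
        if col not in df.columns:
            raise ValueError(f"metadata file {path} lacks required column {col!r}")
    _check_unique(list(df["gene"]), "gene")
    df["category"] = df["category"].fillna("")
    df["is_duf"] = df["is_duf"].astype(bool)
    return df.reset_index(drop=True)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_env(path: str | Path) -> pd.DataFrame:
    """Environmental factors x samples table."""
    return _read_tsv(path)


def write_env(env: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(env, path, index_label="factor")


def _read_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    if df.isna().any().any():
        bad = df.isna().stack()
        row, col = bad[bad].index[0]
        raise ValueError(f"{path}: missing/ragged cell at row {row!r}, column {col!r}")
    return df.astype(float)


def _write_tsv(df: pd.DataFrame, path: str | Path, index_label: str) -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


# ------------------------------------------------------------ normalization


def relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Scale each sample column to sum 1; zeros are preserved.

    Per-sample scaling is strictly positive, so within-sample ranks (and hence
    downstream Spearman correlations) are unchanged.
    """
    sums = table.values.sum(axis=0)
    zero = np.flatnonzero(sums <= 0)
    if zero.size:
        raise ValueError(f"all-zero sample column {table.samples[zero[0]]!r}")
    return AbundanceTable(list(table.genes), list(table.samples), table.values / sums)


def classify_prevalence(
    table: AbundanceTable,
    min_prevalence: int = 25,
    min_abundance: float = 0.0,
) -> dict[str, PrevalenceClass]:
    """Classify every gene as core / noncore / excluded by detection count.

    "Detected" means abundance strictly greater than ``min_abundance``
    (default 0, i.e. any nonzero value counts).
    """
    n = table.n_samples
    if min_prevalence > n:
        raise ValueError(f"min_prevalence {min_prevalence} exceeds n_samples {n}")
    presence = (table.values > min_abundance).sum(axis=1)
    out: dict[str, PrevalenceClass] = {}
    for gene, pres in zip(table.genes, presence):
        pres = int(pres)
        if pres == n:
            label = Prevalence.CORE
        elif pres >= min_prevalence:
            label = Prevalence.NONCORE
        else:
            label = Prevalence.EXCLUDED
        out[gene] = PrevalenceClass(label, pres)
    return out


def filter_excluded(
    table: AbundanceTable, prevalence: dict[str, PrevalenceClass]
) -> AbundanceTable:
    """Drop excluded genes; the retained genes feed network construction."""
    keep = [g for g in table.genes if prevalence[g].label is not Prevalence.EXCLUDED]
    if not keep:
        raise ValueError("no genes pass the prevalence filter")
    return table.subset(keep)
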