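import numpy as np
import pytest

import metagenet as mg


@pytest.fixture(scope="session")
def small_dataset():
    """Four planted clusters, 25 genes each, all-core, with DUF labels."""
    spec = mg.SyntheticSpec(
        n_clusters=4, genes_per_cluster=25, n_background_genes=20,
        n_excluded_genes=0, frac_core=1.0, duf_fraction=0.2, seed=7,
    )
    return mg.generate_dataset(spec)


@pytest.fixture(scope="session")
def small_network(small_dataset):
    """Network on the planted clusters, thresholded on raw Spearman rho."""
    ds = small_dataset
    corr = mg.spearman_matrix(ds.abundance)
    prev = mg.classify_prevalence(ds.abundance)
    return mg.build_network(
        corr, threshold=0.6, matrix="rho", prevalence=prev, metadata=ds.metadata
    )


def make_table(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return mg.AbundanceTable(genes, samples, values)
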