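import numpy as np
import pandas as pd
import pytest

import nbburden as nb


@pytest.fixture(scope="session")
def toy_bins():
    """Two chromosomes gridded at 1 Mb: chr1 has 3 bins, chr2 has 2."""
    return nb.make_bins({"chrA": 3_000_000, "chrB": 2_500_000}, 1_000_000)


@pytest.fixture(scope="session")
def default_sim():
    """One seeded run of the default synthetic study (2000 bins)."""
    return nb.simulate_dataset(nb.SyntheticConfig(), seed=7)


@pytest.fixture(scope="session")
def default_fit(default_sim):
    """Counts and a fitted constant-sigma NB regression for default_sim."""
    counts = nb.count_mutations(default_sim.catalog, default_sim.bins)
    scores = default_sim.truth["scores"][:, :3]
    model = nb.fit_nb_regression(scores, counts.counts("D1"))
    return counts, scores, model


def make_catalog(rows):
    """rows: iterable of (chrom, pos, sample, disease)."""
    return pd.DataFrame(rows, columns=["chrom", "pos", "sample", "disease"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
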