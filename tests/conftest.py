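import numpy as np
import pytest

from tadlamina.contact_io import BinTable, ContactMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_symmetric_matrix(rng, n, density=1.0, chrom="chrT", resolution=25_000):
    """Dense random symmetric nonnegative matrix with all bins valid."""
    a = rng.gamma(2.0, 1.0, size=(n, n))
    if density < 1.0:
        a *= rng.random((n, n)) < density
    a = np.triu(a)
    a = a + a.T - np.diag(np.diag(a))
    return ContactMatrix(
        chrom=chrom,
        resolution=resolution,
        values=a,
        valid_mask=np.ones(n, dtype=bool),
    )


@pytest.fixture
def two_bin_table(tmp_path):
    bins = BinTable.from_chrom_sizes({"chrT": 50_000}, 25_000)
    return bins


@pytest.fixture(scope="session")
def default_truth_and_maps():
    """The default synthetic chromosome: 10 Mb at 25 kb, depth 5e6, seed 7."""
    from tadlamina.synthetic_data import GenomeSpec, generate_truth, render_contact_map

    spec = GenomeSpec()
    truth = generate_truth(spec)
    maps = {
        "wt": render_contact_map(truth, "wt", noise_seed=8),
        "ko": render_contact_map(truth, "ko", noise_seed=9),
    }
    return truth, maps
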