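import numpy as np
import pandas as pd
import pytest

from cislink.annotation_io import FeatureSet, GenomicFeature
from cislink.diffexpr import ExpressionMatrix
from cislink.synthetic import SimConfig, simulate_dataset


def make_feature(fid, chrom="chr1", start=1000, end=2000, biotype="other", **kw):
    return GenomicFeature(feature_id=fid, chrom=chrom, start=start, end=end,
                          biotype=biotype, **kw)


@pytest.fixture
def tiny_matrix():
    """4 features x 6 samples (3 case, 3 control), TPM."""
    rng = np.random.default_rng(7)
    vals = pd.DataFrame(
        rng.uniform(1, 100, size=(4, 6)),
        index=[f"g{i}" for i in range(4)],
        columns=[f"s{i}" for i in range(6)],
    )
    cond = {f"s{i}": ("case" if i < 3 else "control") for i in range(6)}
    return ExpressionMatrix(vals, cond, unit="TPM")


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition simulated dataset, shared across tests."""
    return simulate_dataset(SimConfig())


@pytest.fixture(scope="session")
def random_feature_sets():
    """~500 random loci split into lncRNAs and mRNAs, for pairing oracles."""
    rng = np.random.default_rng(123)
    lncs, mrnas = [], []
    for i in range(200):
        chrom = f"chr{rng.integers(1, 4)}"
        start = int(rng.integers(1, 2_000_000))
        length = int(rng.integers(200, 20_000))
        lncs.append(make_feature(f"L{i}", chrom, start, start + length, "lncRNA"))
    for i in range(300):
        chrom = f"chr{rng.integers(1, 4)}"
        start = int(rng.integers(1, 2_000_000))
        length = int(rng.integers(500, 50_000))
        mrnas.append(make_feature(f"M{i}", chrom, start, start + length, "mRNA"))
    return FeatureSet(lncs), FeatureSet(mrnas)
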