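import numpy as np
import pytest

from sugibs.genotype_io import (
    MISSING,
    GenotypeMatrix,
    SampleRecord,
    VariantRecord,
)


def make_panel(values, alleles=None, ids=None):
    """Build a GenotypeMatrix from a raw array, with synthetic metadata."""
    values = np.asarray(values, dtype=np.int8)
    m, n = values.shape
    if alleles is None:
        alleles = [("A", "C")] * m
    variants = [
        VariantRecord("1", ids[i] if ids else f"snp{i + 1}", 0.0, i + 1, *alleles[i])
        for i in range(m)
    ]
    samples = [SampleRecord("fam", f"ind{j + 1}") for j in range(n)]
    return GenotypeMatrix(values, variants, samples)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_panel(rng):
    """30 SNPs x 12 samples with ~8% missing calls."""
    vals = rng.choice(
        np.array([-1, 0, 1, MISSING], dtype=np.int8),
        size=(30, 12),
        p=[0.3, 0.32, 0.3, 0.08],
    )
    return make_panel(vals)


@pytest.fixture
def observed_panel(rng):
    """Fully observed 40 SNPs x 10 samples."""
    vals = rng.choice(np.array([-1, 0, 1], dtype=np.int8), size=(40, 10))
    return make_panel(vals)
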