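import numpy as np
import pytest

from gemot.data import AlignedDataset, LabeledMatrix, VariantTable


def labeled(values, row_prefix="r", col_prefix="S"):
    values = np.asarray(values, dtype=float)
    return LabeledMatrix(
        values,
        [f"{row_prefix}{i}" for i in range(values.shape[0])],
        [f"{col_prefix}{j}" for j in range(values.shape[1])],
    )


def make_variant_table(geno_values, col_prefix="S"):
    geno_values = np.asarray(geno_values, dtype=float)
    n = geno_values.shape[0]
    vids = [f"v{i}" for i in range(n)]
    lm = LabeledMatrix(
        geno_values, vids, [f"{col_prefix}{j}" for j in range(geno_values.shape[1])]
    )
    return VariantTable(vids, ["1"] * n, [(i + 1) * 1000 for i in range(n)], lm)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    """20 variants x 40 transcripts x 10 traits over 60 strains, pure noise."""
    n = 60
    geno = make_variant_table(rng.binomial(1, 0.5, size=(20, n)).astype(float))
    expr = labeled(rng.standard_normal((40, n)), row_prefix="g")
    traits = labeled(rng.standard_normal((10, n)), row_prefix="p")
    return AlignedDataset(geno, expr, traits)
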