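import numpy as np
import pandas as pd
import pytest

from beachflow.simdata import GenotypeMatrix, TagMap


def make_matrix(codes, localities=None, habitats=None, snp_ids=None):
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    samples = pd.DataFrame({
        "individual": [f"ind{i:03d}" for i in range(n)],
        "locality": localities if localities is not None else [1] * n,
        "habitat": habitats if habitats is not None else
        ["B"] * (n // 2) + ["I"] * (n - n // 2),
    })
    ids = snp_ids or [f"snp{j:04d}" for j in range(m)]
    return GenotypeMatrix(codes, samples, ids)


def make_tagmap(snp_ids, tag_ids, offsets, contig_length=300):
    return TagMap(pd.DataFrame({"snp_id": snp_ids, "tag_id": tag_ids,
                                "offset": offsets}),
                  contig_length=contig_length)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_matrix(rng):
    """12 individuals x 40 SNPs with some missingness, two habitats."""
    codes = rng.integers(0, 3, size=(12, 40)).astype(np.int8)
    miss = rng.random((12, 40)) < 0.05
    codes[miss] = -1
    return make_matrix(codes)
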