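import numpy as np
import pandas as pd
import pytest

from cqbatch.data import CountTable, StudyDesign


def make_table(counts, sample_ids=None, otu_ids=None):
    counts = np.asarray(counts)
    n, m = counts.shape
    sample_ids = sample_ids or [f"s{i+1}" for i in range(n)]
    otu_ids = otu_ids or [f"o{j+1}" for j in range(m)]
    return CountTable(pd.DataFrame(counts, index=sample_ids, columns=otu_ids))


def make_design(batches, covariates=None, **kwargs):
    idx = list(batches.keys())
    batch = pd.Series({s: g for s, g in batches.items()})
    cov = pd.DataFrame(covariates or {}, index=idx)
    return StudyDesign(batch=batch, covariates=cov, **kwargs)


@pytest.fixture
def small_table():
    rng = np.random.default_rng(42)
    counts = rng.poisson(20, size=(12, 5))
    counts[0, 0] = 0
    return make_table(counts)


@pytest.fixture
def small_design(small_table):
    ids = small_table.sample_ids
    batch = pd.Series(["A"] * 6 + ["B"] * 6, index=ids)
    rng = np.random.default_rng(7)
    cov = pd.DataFrame({"age": rng.normal(40, 10, 12)}, index=ids)
    return StudyDesign(batch=batch, covariates=cov)
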