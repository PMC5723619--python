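import numpy as np
import pandas as pd
import pytest

from broodscan.datamodel import MISSING, GenotypeDataset


def make_random_dataset(n_samples: int, n_loci: int, rng, missing_rate: float = 0.0,
                        with_meta: bool = True) -> GenotypeDataset:
    """Random biallelic dataset with optional missingness and simple metadata."""
    p = rng.uniform(0.1, 0.9, size=n_loci)
    counts = rng.binomial(2, p[None, :], size=(n_samples, n_loci))
    calls = np.empty((n_samples, n_loci, 2), dtype=np.int16)
    calls[:, :, 0] = np.where(counts >= 1, 0, 1)
    calls[:, :, 1] = np.where(counts == 2, 0, 1)
    if missing_rate > 0:
        mask = rng.random((n_samples, n_loci)) < missing_rate
        calls[mask] = MISSING
    sample_ids = [f"s{i:03d}" for i in range(n_samples)]
    ds = GenotypeDataset(
        sample_ids,
        [f"L{j:04d}" for j in range(n_loci)],
        calls,
        allele_names=[["A", "G"]] * n_loci,
    )
    if with_meta:
        years = [2000 + 3 * (i % 4) for i in range(n_samples)]
        meta = pd.DataFrame(
            {
                "brood_year": years,
                "broodline": ["A"] * n_samples,
                "generation": [(y - 2000) // 3 for y in years],
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        ds.attach_metadata(meta)
    return ds


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
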