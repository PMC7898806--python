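import numpy as np
import pandas as pd
import pytest

from loticom import SampleMetadata, TaxaTable, read_newick


@pytest.fixture
def tiny_table() -> TaxaTable:
    """3 taxa x 4 samples, one sample per habitat."""
    data = pd.DataFrame(
        {
            "s_FL": [10.0, 0.0, 2.0],
            "s_PA": [0.0, 5.0, 2.0],
            "s_BF": [0.0, 5.0, 2.0],
            "s_SE": [30.0, 0.0, 2.0],
        },
        index=["otu1", "otu2", "otu3"],
    )
    return TaxaTable(data)


@pytest.fixture
def tiny_meta() -> SampleMetadata:
    return SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": ["s_FL", "s_PA", "s_BF", "s_SE"],
                "site": ["site01"] * 4,
                "habitat": ["FL", "PA", "BF", "SE"],
                "replicate": [1, 1, 1, 1],
            }
        )
    )


@pytest.fixture
def three_tip_tree():
    return read_newick("(A:0.5,(B:0.2,C:0.2):0.3);")


@pytest.fixture
def replicate_table_meta():
    """One site, one habitat, 4 replicates; engineered prevalence boundaries."""
    rng = np.random.default_rng(42)
    samples = [f"site01_BF_r{r}" for r in range(1, 5)]
    data = pd.DataFrame(
        {
            s: rng.integers(1, 50, size=6).astype(float) for s in samples
        },
        index=[f"otu{i}" for i in range(1, 7)],
    )
    # otu1: all 4 replicates; otu2: 3 of 4 (75%); otu3: 2 of 4; otu4: 1 of 4
    data.loc["otu2", samples[0]] = 0.0
    data.loc["otu3", samples[:2]] = 0.0
    data.loc["otu4", samples[:3]] = 0.0
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": samples,
                "site": ["site01"] * 4,
                "habitat": ["BF"] * 4,
                "replicate": [1, 2, 3, 4],
            }
        )
    )
    return TaxaTable(data), meta


def random_table(rng: np.random.Generator, n_taxa: int = 12, n_samples: int = 6,
                 habitats=("FL", "PA", "BF", "SE")) -> tuple[TaxaTable, SampleMetadata]:
    """Random sparse counts with habitat labels cycling over samples."""
    counts = rng.integers(0, 30, size=(n_taxa, n_samples)).astype(float)
    counts[rng.random(counts.shape) < 0.3] = 0.0
    counts[:, counts.sum(axis=0) == 0] = 1.0  # no empty samples
    samples = [f"s{j}" for j in range(n_samples)]
    table = TaxaTable(
        pd.DataFrame(counts, index=[f"otu{i}" for i in range(n_taxa)], columns=samples)
    )
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": samples,
                "site": [f"site{j:02d}" for j in range(n_samples)],
                "habitat": [habitats[j % len(habitats)] for j in range(n_samples)],
                "replicate": [1] * n_samples,
            }
        )
    )
    return table, meta
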