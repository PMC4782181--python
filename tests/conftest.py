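import numpy as np
import pandas as pd
import pytest

from wtonet import ExpressionMatrix, SyntheticConfig


@pytest.fixture
def small_tsv(tmp_path):
    """3-gene x 4-sample expression TSV."""
    p = tmp_path / "expr.tsv"
    p.write_text(
        "gene_id\tS1\tS2\tS3\tS4\n"
        "G1\t1.0\t2.0\t3.0\t4.0\n"
        "G2\t0.5\t0.5\t0.5\t0.5\n"
        "G3\t4.0\t3.0\t2.0\t1.0\n"
    )
    return p


@pytest.fixture
def noise_matrix():
    """200 i.i.d.-noise genes x 20 samples (no structure)."""
    rng = np.random.default_rng(1234)
    df = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(200, 20)),
        index=[f"G{i:03d}" for i in range(200)],
        columns=[f"S{j:02d}" for j in range(20)],
    )
    return ExpressionMatrix(df, "microarray")


@pytest.fixture
def planted_config():
    """Default study conditions: 10 datasets, 2 modules of 5 GRFs."""
    return SyntheticConfig(seed=20240901)


@pytest.fixture
def small_planted_config():
    """Cheaper planted structure for single-dataset tests."""
    return SyntheticConfig(
        seed=77, n_datasets=3, n_grfs=12, n_targets=60,
        samples_per_dataset=[20, 20, 20],
    )
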