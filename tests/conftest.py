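import numpy as np
import pandas as pd
import pytest

from synaptomics import AbundanceMatrix, OmicsGroundTruth, StudyDesign, simulate_level


def make_matrix(values, region="M1", level="protein", gene_ids=None):
    """Small AbundanceMatrix from a (features x 2n) array: first half PME."""
    values = np.asarray(values, float)
    n_feat, n_samp = values.shape
    assert n_samp % 2 == 0
    half = n_samp // 2
    names = [f"PME_M_{i + 1}" for i in range(half)] + [f"PSE_M_{i + 1}" for i in range(half)]
    meta = pd.DataFrame({
        "group": ["PME"] * half + ["PSE"] * half,
        "sex": ["M"] * n_samp,
        "region": [region] * n_samp,
    }, index=names)
    fids = [f"F{i}" for i in range(n_feat)]
    genes = gene_ids if gene_ids is not None else [f"G{i}" for i in range(n_feat)]
    df = pd.DataFrame(values, index=pd.Index(fids, name="feature_id"), columns=names)
    return AbundanceMatrix(values=df, sample_meta=meta,
                           gene_ids=pd.Series(genes, index=df.index),
                           region=region, level=level)


@pytest.fixture(scope="session")
def small_design():
    return StudyDesign()


@pytest.fixture(scope="session")
def null_dataset(small_design):
    """5,000 null features under the 16-sample design (no planted effects)."""
    truth = OmicsGroundTruth(n_features=5000, frac_differential=0.0,
                             noise_sd=0.3, seed=11)
    matrices, truth = simulate_level(small_design, truth)
    return matrices, truth


@pytest.fixture(scope="session")
def planted_dataset(small_design):
    """1,000 features, 10% differential at |log2FC| = 1, sd 0.3."""
    truth = OmicsGroundTruth(n_features=1000, frac_differential=0.1,
                             effect_size_log2=1.0, noise_sd=0.3, seed=5)
    matrices, truth = simulate_level(small_design, truth)
    return matrices, truth
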