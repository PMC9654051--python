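import numpy as np
import pandas as pd
import pytest

from crsignature.expression import CountMatrix
from crsignature.synthetic import SyntheticConfig, generate_counts


@pytest.fixture
def tiny_cm() -> CountMatrix:
    """3 genes x 4 samples with hand-set counts and lengths."""
    counts = pd.DataFrame(
        {
            "s1": [10, 0, 7],
            "s2": [20, 5, 14],
            "s3": [10, 5, 7],
            "s4": [40, 10, 28],
        },
        index=["gA", "gB", "gC"],
    )
    lengths = pd.Series([1000, 2500, 2000], index=["gA", "gB", "gC"])
    return CountMatrix(counts=counts, gene_lengths=lengths)


@pytest.fixture
def tiny_meta() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "diet": ["control", "CR", "control", "CR"],
            "tissue": ["hypothalamus", "hypothalamus", "amygdala", "amygdala"],
        }
    )


@pytest.fixture(scope="session")
def small_run():
    """One small simulated experiment shared across tests (500 genes, seed 7)."""
    cfg = SyntheticConfig(n_genes=500, frac_signature=0.02, frac_tissue_dep=0.02,
                          effect_fold=3.0, seed=7)
    cm, meta, truth = generate_counts(cfg)
    return cfg, cm, meta, truth


def balanced_design_labels(n_per_cell: int = 5):
    """Diet and tissue labels of the standard 2x4 design, n per cell."""
    diets, tissues = [], []
    for t in ("hypothalamus", "amygdala", "pituitary", "adrenal"):
        for d in ("control", "CR"):
            diets += [d] * n_per_cell
            tissues += [t] * n_per_cell
    return np.array(diets), np.array(tissues)
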