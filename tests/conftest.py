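import numpy as np
import pandas as pd
import pytest

from omicross.datatypes import ExpressionMatrix
from omicross.simulate import SimConfig, generate_dataset


def expr_from_log2(values, genes, samples, layer="mRNA") -> ExpressionMatrix:
    """Build an ExpressionMatrix whose log2(x+1) equals `values` exactly."""
    arr = np.power(2.0, np.asarray(values, dtype=float)) - 1.0
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples), layer)


@pytest.fixture(scope="session")
def small_dataset():
    """A small two-subtype dataset with strong separation, shared across tests."""
    cfg = SimConfig(n_tumor=60, n_normal=16, n_mrna=150, n_mirna=50, n_lncrna=150,
                    k_true=2, subtype_shift=3.0, noise_sd=1.0, n_triplets=6, seed=42)
    layers, annot, truth = generate_dataset(cfg)
    return cfg, layers, annot, truth
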