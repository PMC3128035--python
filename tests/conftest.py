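import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from degrank.matrix import LOG2, ExpressionMatrix
from degrank.ranking import ClassDesign


def make_log2_matrix(values, sample_types=None, probe_ids=None):
    """Small helper: build a log2 ExpressionMatrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    if sample_types is None:
        half = n // 2
        sample_types = ["A"] * half + ["B"] * (n - half)
    sample_ids = [f"s{i}_{t}" for i, t in enumerate(sample_types)]
    if probe_ids is None:
        probe_ids = [f"p{i:03d}" for i in range(m)]
    df = pd.DataFrame(values, index=probe_ids, columns=sample_ids)
    meta = pd.DataFrame(
        {"type": sample_types, "site": "1", "platform": "T"}, index=sample_ids
    )
    return ExpressionMatrix(df, LOG2, meta)


def make_design(matrix, type1="A", type2="B"):
    return ClassDesign.from_samples(matrix.samples, type1, type2)


def random_instance(rng, m=50, n1=4, n2=4):
    """Random log2 matrix + design for oracle-equivalence checks."""
    base = rng.uniform(4, 12, size=(m, 1))
    x = base + rng.normal(0, 0.6, size=(m, n1 + n2))
    x[: m // 5, n1:] += rng.normal(1.5, 0.3, size=(m // 5, n2))
    mat = make_log2_matrix(x, ["A"] * n1 + ["B"] * n2)
    return mat, make_design(mat)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
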