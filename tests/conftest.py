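import numpy as np
import pandas as pd
import pytest

from zdosage.containers import ExpressionMatrix, validate_annotation


@pytest.fixture
def tiny_annotation():
    return validate_annotation(
        pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3", "g4"],
                "chromosome": ["1", "1", "Z", "Z"],
                "position_bp": [100, 200, 100, 200],
                "gc_fraction": [0.4, 0.5, 0.45, 0.55],
                "exon_length_bp": [1000, 2000, 1500, 2500],
            }
        )
    )


@pytest.fixture
def tiny_counts(tiny_annotation):
    values = pd.DataFrame(
        {
            "M1": [10, 20, 30, 40],
            "M2": [12, 18, 28, 44],
            "F1": [11, 19, 15, 20],
            "F2": [9, 21, 14, 22],
        },
        index=tiny_annotation.index,
    )
    samples = pd.DataFrame(
        {
            "sex": ["M", "M", "F", "F"],
            "group": ["a", "b", "a", "b"],
            "library_size": [1_000_000] * 4,
        },
        index=pd.Index(["M1", "M2", "F1", "F2"], name="sample_id"),
    )
    return ExpressionMatrix(values, samples, unit="counts")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
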