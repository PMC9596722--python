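import numpy as np
import pandas as pd
import pytest

from clockpe.io import ExpressionMatrix, PhenotypeTable


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    """2 genes x 3 samples literal matrix."""
    return ExpressionMatrix(
        pd.DataFrame(
            [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]],
            index=["g1", "g2"],
            columns=["s1", "s2", "s3"],
        ),
        cohort_label="tiny",
    )


@pytest.fixture
def small_cohort() -> tuple[ExpressionMatrix, PhenotypeTable]:
    """8 genes x 12 samples with a clear case shift in two genes."""
    rng = np.random.default_rng(42)
    genes = [f"G{i}" for i in range(8)]
    samples = [f"s{i}" for i in range(12)]
    values = rng.normal(8.0, 0.5, size=(8, 12))
    values[0, 6:] += 1.5  # G0 up in cases
    values[1, 6:] -= 1.5  # G1 down in cases
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), cohort_label="small"
    )
    pheno = PhenotypeTable(
        pd.DataFrame(
            {
                "condition": ["non-PE"] * 6 + ["PE"] * 6,
                "preterm": [False] * 12,
                "dataset_id": "small",
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )
    return expr, pheno
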