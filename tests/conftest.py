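import numpy as np
import pandas as pd
import pytest

from peacs import ExpressionMatrix, PerturbationDesign


@pytest.fixture
def rng():
    return np.random.default_rng(20151004)


@pytest.fixture
def ct_matrix():
    """A tiny CT-scale matrix with a reference gene (hand-checkable values)."""
    return ExpressionMatrix(
        values=np.array(
            [
                [22.0, 25.0, 18.0],
                [24.0, 24.0, 18.5],
                [21.0, 26.0, 17.5],
                [23.0, 25.5, 18.0],
            ]
        ),
        gene_ids=["TF1", "TF2", "GAPDH"],
        sample_ids=["s1", "s2", "s3", "s4"],
        scale="ct",
    )


def make_design(records):
    return PerturbationDesign(
        pd.DataFrame(
            records,
            columns=[
                "sample_id",
                "perturbation",
                "target_gene",
                "hairpin",
                "replicate",
                "is_control",
            ],
        )
    )


@pytest.fixture
def small_screen(rng):
    """6 samples × 4 genes, 2 hairpins × 2 reps + 2 controls (log2 scale)."""
    values = rng.normal(0, 1, size=(6, 4))
    M = ExpressionMatrix(
        values=values,
        gene_ids=["GA", "GB", "GC", "GD"],
        sample_ids=[f"s{i}" for i in range(6)],
        scale="log2_expr",
    )
    design = make_design(
        [
            ("s0", "shGA_1", "GA", "shGA_1", 1, False),
            ("s1", "shGA_1", "GA", "shGA_1", 2, False),
            ("s2", "shGB_1", "GB", "shGB_1", 1, False),
            ("s3", "shGB_1", "GB", "shGB_1", 2, False),
            ("s4", "shCTRL", "none", "shCTRL", 1, True),
            ("s5", "shCTRL", "none", "shCTRL", 2, True),
        ]
    )
    return M, design
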