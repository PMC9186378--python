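import numpy as np
import pandas as pd
import pytest

from tammune import synth
from tammune.matrix import ExpressionMatrix


@pytest.fixture(scope="session")
def sc_cohort():
    """Small differentiation cohort with planted markers and one CNV segment."""
    cfg = synth.ScSimConfig(
        n_cells=400,
        n_genes=500,
        early_effect_log2fc=2.0,
        late_effect_log2fc=2.0,
        noise_sd=0.2,
        cnv_segments=[(100, 250, 2.0)],
        seed=101,
    )
    return synth.gen_sc_cohort(cfg)


@pytest.fixture(scope="session")
def traj_cohort():
    """Differentiation cohort without copy-number segments, so the
    differentiation axis is the dominant structure for embedding tests."""
    cfg = synth.ScSimConfig(
        n_cells=300,
        n_genes=400,
        early_effect_log2fc=2.0,
        late_effect_log2fc=2.0,
        noise_sd=0.3,
        seed=77,
    )
    return synth.gen_sc_cohort(cfg)


@pytest.fixture(scope="session")
def bulk_cohort():
    """Bulk mixture cohort with planted hot/cold phenotype."""
    cfg = synth.BulkSimConfig(
        n_samples=120, n_genes=300, noise_sd=0.2, hot_effect_log2fc=2.0, seed=202
    )
    return synth.gen_bulk_cohort(cfg)


@pytest.fixture(scope="session")
def subtype_cohort():
    """Bulk cohort with the planted A1/A2/A3 + B structure."""
    cfg = synth.BulkSimConfig(
        n_samples=160, n_genes=250, noise_sd=0.2, plant_a_subtypes=3, seed=303
    )
    return synth.gen_bulk_cohort(cfg)


@pytest.fixture
def toy_expr():
    """5 genes x 3 samples with distinct rankings per sample."""
    return ExpressionMatrix(
        pd.DataFrame(
            {
                "s1": [5.0, 4.0, 3.0, 2.0, 1.0],
                "s2": [1.0, 2.0, 3.0, 4.0, 5.0],
                "s3": [2.0, 5.0, 1.0, 4.0, 3.0],
            },
            index=list("ABCDE"),
        )
    )


def best_permutation_agreement(pred: pd.Series, truth: pd.Series) -> float:
    """Label agreement maximized over permutations of the A subtypes."""
    from itertools import permutations

    best = 0.0
    for perm in permutations(["A1", "A2", "A3"]):
        mapping = dict(zip(["A1", "A2", "A3"], perm))
        mapping["B"] = "B"
        best = max(best, float((pred.map(mapping) == truth).mean()))
    return best
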