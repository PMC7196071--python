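import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)

from actbenefit import (ClinicalRecord, CohortDataset, ExpressionMatrix,
                        SyntheticConfig, generate_cohort, label_cohort)


@pytest.fixture
def toy_matrix():
    return ExpressionMatrix(
        gene_ids=["GA", "GB", "GC"],
        sample_ids=["s1", "s2"],
        values=np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
        scale="log2",
    )


def make_record(sample_id="s1", act=True, rfs=48.0, event=False, stage="II", **kw):
    return ClinicalRecord(sample_id=sample_id, act=act, rfs_months=rfs,
                          relapse_event=event, tnm_stage=stage, **kw)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def small_cohort():
    """200-patient default-signal cohort reused by read-only tests."""
    return generate_cohort(SyntheticConfig(n_patients=200, n_genes=40), seed=7)


@pytest.fixture(scope="session")
def labeled_small_cohort(small_cohort):
    dataset, _ = small_cohort
    return label_cohort(dataset)


def separable_cohort(n=60, seed=0):
    """Tiny cohort whose first gene perfectly separates benefit from futile."""
    rng = np.random.default_rng(seed)
    half = n // 2
    g0 = np.concatenate([rng.normal(8, 0.3, half), rng.normal(4, 0.3, n - half)])
    noise = rng.normal(6, 1, size=(4, n))
    values = np.vstack([g0, noise])
    expr = ExpressionMatrix([f"G{i}" for i in range(5)],
                            [f"s{i:03d}" for i in range(n)], values)
    recs = [make_record(sample_id=f"s{i:03d}", act=bool(i % 2),
                        rfs=50.0, event=False, stage="II" if i % 3 else "III")
            for i in range(n)]
    labels = ["benefit"] * half + ["futile"] * (n - half)
    return CohortDataset(expr, recs), labels


@pytest.fixture
def separable():
    return separable_cohort()
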