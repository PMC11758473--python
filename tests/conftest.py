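import numpy as np
import pandas as pd
import pytest

from emodyad.apim import XNAMES, ApimSpec, DesignMatrix, build_design
from emodyad.synthetic import SyntheticConfig, generate_dyads


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic 60-dyad cohort shared across read-only tests."""
    return generate_dyads(SyntheticConfig(n_dyads=60, n_days=10, seed=42))


def make_regression_design(rng: np.random.Generator, n: int,
                           beta1: np.ndarray, beta2: np.ndarray,
                           resid_cov: np.ndarray,
                           miss_rate: float = 0.0,
                           hetero: bool = False) -> tuple[DesignMatrix, np.ndarray]:
    """Direct bivariate-regression fixture on the standard 7-column design."""
    p = len(XNAMES)
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    E = rng.multivariate_normal([0.0, 0.0], resid_cov, size=n)
    if hetero:
        scale = np.abs(X[:, 1])
        E = E * scale[:, None]
    Y = np.column_stack([X @ beta1 + E[:, 0], X @ beta2 + E[:, 1]])
    if miss_rate > 0:
        mask = rng.random((n, 2)) < miss_rate
        both = mask.all(axis=1)
        mask[both, rng.integers(0, 2, both.sum())] = False  # keep >=1 outcome
        Y = np.where(mask, np.nan, Y)
    design = DesignMatrix([f"d{i}" for i in range(n)], X, XNAMES, Y,
                          ("y_adol", "y_cg"), {})
    return design, np.column_stack([beta1, beta2])


def cohort_frames(dyads):
    """Summaries + baseline frames for a generated cohort."""
    from emodyad.emometrics import summarize_dyads

    summaries = summarize_dyads(dyads)
    base = pd.DataFrame([vars(b) for d in dyads
                         for b in (d.adolescent_baseline, d.caregiver_baseline)
                         if b is not None])
    return summaries, base


def fit_cohort(dyads, valence="negative", symptom="anxious"):
    from emodyad.apim import fit_apim, robust_se, standardize

    summaries, base = cohort_frames(dyads)
    design = build_design(summaries, base, ApimSpec(valence, symptom))
    fit = standardize(robust_se(fit_apim(design), design), design)
    return design, fit
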