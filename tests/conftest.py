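import numpy as np
import pandas as pd
import pytest

from mirsig.io import ClinicalCohort, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_survival(rng, n=60, p=5, beta=None, censor_rate=0.25, base=10.0):
    """Small random proportional-hazards dataset (no ties)."""
    X = rng.normal(size=(n, p))
    if beta is None:
        beta = np.zeros(p)
    beta = np.asarray(beta, dtype=float)
    T = rng.exponential(base / np.exp(X @ beta))
    if censor_rate > 0:
        C = rng.exponential(base / censor_rate * 0.8, n)
        time = np.minimum(T, C)
        event = (T <= C).astype(int)
    else:
        time, event = T, np.ones(n, dtype=int)
    if event.sum() == 0:
        event[np.argmin(time)] = 1
    return time, event, X


@pytest.fixture
def paired_fixture(rng):
    """40-feature / 6-pair expression matrix with 8 planted shifts."""
    G, n = 40, 6
    normal = rng.normal(8.0, 1.0, (G, n))
    diffs = rng.normal(0.0, 0.6, (G, n))
    diffs[:8] += 2.0
    tum = normal + diffs
    ids = [f"g{i:02d}" for i in range(G)]
    cols = [f"T{i}" for i in range(n)] + [f"N{i}" for i in range(n)]
    expr = ExpressionMatrix(pd.DataFrame(np.hstack([tum, normal]), index=ids, columns=cols))
    pairing = {f"P{i}": (f"T{i}", f"N{i}") for i in range(n)}
    return expr, pairing, ids[:8]


def make_cohort(rng, n=40, n_features=3, beta=(0.8, 0.0, 0.0), name="cohort"):
    ids = [f"f{j}" for j in range(n_features)]
    X = rng.normal(6.0, 1.0, (n, n_features))
    lp = (X - X.mean(axis=0)) @ np.asarray(beta, dtype=float)
    T = rng.exponential(10.0 / np.exp(lp))
    C = rng.exponential(30.0, n)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    samples = [f"s{i:03d}" for i in range(n)]
    resp = rng.choice(["CR", "PR", "SD", "PD"], size=n, p=[0.05, 0.3, 0.45, 0.2])
    expr = ExpressionMatrix(pd.DataFrame(X.T, index=ids, columns=samples))
    clin = ClinicalCohort(
        pd.DataFrame({"pfs_months": np.maximum(time, 1e-3), "event": event,
                      "response": resp}, index=samples),
        name=name,
    )
    return expr, clin
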