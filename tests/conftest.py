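import numpy as np
import pandas as pd
import pytest

import lrrksig as L


@pytest.fixture(scope="session")
def small_bundle():
    """One modest synthetic cohort shared across read-only tests."""
    return L.generate_bundle(seed=7, n_proteins=120, n_sites=120)


@pytest.fixture(scope="session")
def small_sheet():
    return L.generate_cohort(seed=3)


@pytest.fixture()
def toy_table():
    """A tiny complete log2-scale table with two groups of three samples."""
    rng = np.random.default_rng(11)
    vals = pd.DataFrame(rng.normal(20, 1, (8, 6)),
                        index=[f"F{i}" for i in range(8)],
                        columns=[f"s{i}" for i in range(6)])
    sheet = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(6)],
        "group": ["G2019S_L2PD"] * 3 + ["CTRL"] * 3,
    })
    return L.IntensityTable(vals, scale="log2"), sheet


def three_class_problem(seed, n_samples=(30, 20, 40), n_features=40, n_inf=5,
                        effect=2.0):
    """Samples x features frame with planted informative columns.

    Class B sits between A and C on half the informative features and apart
    on the rest, mirroring the cohort's carrier / disease marker mix.
    """
    rng = np.random.default_rng(seed)
    labels = np.repeat(["A", "B", "C"], n_samples)
    n = len(labels)
    X = rng.normal(0.0, 1.0, (n, n_features))
    for j in range(n_inf):
        shift_b = effect if j % 2 == 0 else 0.0
        X[labels == "A", j] += effect
        X[labels == "B", j] += shift_b
    cols = [f"INF{j}" for j in range(n_inf)] + \
           [f"NOISE{j}" for j in range(n_features - n_inf)]
    return pd.DataFrame(X, columns=cols), labels
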