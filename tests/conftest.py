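import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import lferkit as lk

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_mols():
    """Packaged structures with hand-verified descriptor values."""
    return lk.fixture_records()


def ols_normal_equations(X, y):
    """Independent least-squares oracle: explicit normal equations with an
    intercept column, solved directly. Kept free of any lferkit code path."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    design = np.column_stack([np.ones(len(X)), X])
    beta = np.linalg.solve(design.T @ design, design.T @ y)
    return beta[0], beta[1:]


def loo_press_brute_force(X, y):
    """Literal leave-one-out PRESS: refit the OLS without each row."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    press = 0.0
    preds = np.empty(len(y))
    for i in range(len(y)):
        keep = np.arange(len(y)) != i
        c, b = ols_normal_equations(X[keep], y[keep])
        preds[i] = c + X[i] @ b
        press += (y[i] - preds[i]) ** 2
    return press, preds


@pytest.fixture()
def random_tables():
    """Small random regression tables for oracle comparisons."""
    rng = np.random.default_rng(20240917)

    def make(n_tables, n_max=20, p_max=4):
        tables = []
        for _ in range(n_tables):
            p = int(rng.integers(1, p_max + 1))
            n = int(rng.integers(p + 3, n_max + 1))
            X = rng.normal(size=(n, p))
            beta = rng.normal(size=p)
            y = X @ beta + rng.normal(scale=0.5, size=n) + rng.normal()
            cols = [f"d{j}" for j in range(p)]
            df = pd.DataFrame(X, columns=cols)
            df.insert(0, "id", [f"c{i}" for i in range(n)])
            df["y"] = y
            tables.append((df, cols))
        return tables

    return make
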