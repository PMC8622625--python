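import numpy as np
import pandas as pd
import pytest

from ftlipid import simulate


@pytest.fixture(scope="session")
def small_study():
    """A clean (ambiguity-free) small paired study."""
    cfg = simulate.SimConfig(n_patients=8, n_features=80, ambiguity_rate=0.0, seed=42)
    return simulate.generate_study(cfg)


@pytest.fixture(scope="session")
def default_study():
    """A small study with the default ambiguity and censoring."""
    cfg = simulate.SimConfig(n_patients=10, n_features=120, seed=3)
    return simulate.generate_study(cfg)


@pytest.fixture()
def toy_matrix():
    """A tiny features x samples matrix with missing entries."""
    rng = np.random.default_rng(0)
    vals = rng.normal(8.0, 1.0, (12, 6))
    vals[rng.random((12, 6)) < 0.2] = np.nan
    return pd.DataFrame(
        vals,
        index=[f"f{i}" for i in range(12)],
        columns=[f"s{i}" for i in range(6)],
    )


def brute_force_ici_tau(x, y):
    """O(n^2) pair-enumeration oracle for the missing-aware Kendall tau-b.

    Missing entries rank below all observed entries of their vector and tie
    with one another; tau-b's tie-corrected denominator is applied.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    lo_x = np.nanmin(x) - 1 if np.isfinite(x).any() else 0.0
    lo_y = np.nanmin(y) - 1 if np.isfinite(y).any() else 0.0
    xs = np.where(np.isnan(x), lo_x, x)
    ys = np.where(np.isnan(y), lo_y, y)
    conc = disc = tie_x = tie_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = np.sign(xs[i] - xs[j])
            dy = np.sign(ys[i] - ys[j])
            if dx == 0:
                tie_x += 1
            if dy == 0:
                tie_y += 1
            if dx * dy > 0:
                conc += 1
            elif dx * dy < 0:
                disc += 1
    pairs = n * (n - 1) // 2
    denom = np.sqrt(float(pairs - tie_x) * float(pairs - tie_y))
    if denom == 0:
        return float("nan")
    return (conc - disc) / denom
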