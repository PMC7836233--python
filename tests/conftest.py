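import numpy as np
import pandas as pd
import pytest

from foldmorph.io import SubjectTable


@pytest.fixture
def small_df():
    """Two well-formed hemisphere rows of one subject."""
    return pd.DataFrame(
        {
            "subject_id": ["s01", "s01"],
            "hemisphere": ["left", "right"],
            "group": ["control", "control"],
            "age": [30.0, 30.0],
            "sex": [0.0, 0.0],
            "At_mm2": [95000.0, 97000.0],
            "Ae_mm2": [39000.0, 40000.0],
            "T_mm": [2.5, 2.55],
        }
    )


@pytest.fixture
def small_table(small_df):
    return SubjectTable(small_df.copy())


@pytest.fixture
def write_csv(tmp_path):
    """Write a DataFrame to a temp CSV and return its path."""

    def _write(df, name="table.csv", sep=","):
        path = tmp_path / name
        df.to_csv(path, index=False, sep=sep)
        return path

    return _write


def brute_force_ranksum_p(a, b) -> float:
    """Independent oracle: exact two-sided rank-sum p by enumerating all
    assignments of the pooled ranks to the first sample (tie-free data)."""
    from itertools import combinations

    from scipy.stats import rankdata

    a, b = np.asarray(a, float), np.asarray(b, float)
    n, m = len(a), len(b)
    ranks = rankdata(np.concatenate([a, b]))
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    center = n * m / 2
    total = hits = 0
    all_ranks = np.arange(1, n + m + 1)
    for comb in combinations(range(n + m), n):
        u = all_ranks[list(comb)].sum() - n * (n + 1) / 2
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            hits += 1
    return hits / total
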