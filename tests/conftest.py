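"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
import pytest

from pedgibbs.pedigree import PedigreeTable, validate_and_sort
from pedgibbs.simulate import FACTORS


def random_pedigree_frame(n: int, seed: int, p_known: float = 0.7) -> pd.DataFrame:
    """Random valid pedigree: parents drawn among earlier animals."""
    rng = np.random.default_rng(seed)
    animals = [f"A{i:03d}" for i in range(n)]
    sire, dam = [], []
    for i in range(n):
        if i < 4 or rng.random() > p_known:
            sire.append("")
            dam.append("")
        else:
            s, d = rng.choice(i, size=2, replace=False)
            sire.append(animals[s])
            dam.append(animals[d])
    return pd.DataFrame(
        {
            "animal": animals,
            "sire": sire,
            "dam": dam,
            "birth_year": 1990 + np.arange(n) // 10,
            "sex": "unknown",
        }
    )


def brute_force_A(ped: PedigreeTable) -> np.ndarray:
    """Independent recursive-definition oracle for the relationship matrix.

    a(i,j) for i >= j is 0.5 (a(s_i, j) + a(d_i, j)) and
    a(i,i) = 1 + 0.5 a(s_i, d_i), memoized straight from the definition.
    """
    sire, dam = ped.sire, ped.dam

    @lru_cache(maxsize=None)
    def a(i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        if i < j:
            i, j = j, i
        if i == j:
            return 1.0 + 0.5 * a(sire[i], dam[i]) if sire[i] >= 0 and dam[i] >= 0 else 1.0
        return 0.5 * (a(sire[i], j) + a(dam[i], j))

    n = ped.n
    out = np.empty((n, n))
    for i in range(n):
        for j in range(i + 1):
            out[i, j] = out[j, i] = a(i, j)
    return out


def toy_records(
    n: int,
    traits: dict[str, np.ndarray],
    seed: int = 0,
    animals=None,
    **factor_values,
) -> pd.DataFrame:
    """Minimal record frame with constant or supplied factor levels."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"record_id": np.arange(n)})
    df["animal"] = animals if animals is not None else [f"A{i:03d}" for i in range(n)]
    for f in FACTORS:
        v = factor_values.get(f, 1)
        df[f] = v if np.ndim(v) else np.full(n, v)
    for name, vals in traits.items():
        df[name] = vals
    return df


@pytest.fixture(scope="session")
def founder_pedigree():
    frame = pd.DataFrame(
        {
            "animal": [f"A{i:03d}" for i in range(50)],
            "sire": "",
            "dam": "",
            "birth_year": 2000,
            "sex": "unknown",
        }
    )
    return validate_and_sort(frame)


@pytest.fixture(scope="session")
def table2_counts():
    # printed per-class record counts of the 14 ordinal defects
    return {
        "OH": (238, 100, 5),
        "CH": (181, 233, 69),
        "Conv": (252, 122, 38),
        "Diver": (251, 148, 33),
        "CU": (226, 257, 24),
        "CO": (341, 15, 0),
        "PTF": (178, 126, 14),
        "SFF": (144, 255, 40),
        "BN": (374, 82, 11),
        "BW": (363, 108, 5),
        "BUF": (311, 98, 9),
        "CF": (268, 184, 25),
        "Straight": (313, 143, 11),
        "Sloping": (310, 137, 5),
    }


@pytest.fixture(scope="session")
def table5_components():
    # posterior-mean (sigma_pe, sigma_u, sigma_e) and printed h2 per trait
    return {
        "OH": (542.23, 367.04, 1415.60, 0.16),
        "CH": (276.32, 138.89, 784.17, 0.12),
        "Conv": (631.57, 487.25, 944.30, 0.24),
        "Diver": (593.19, 308.43, 853.16, 0.18),
        "CU": (26.07, 32.03, 132.83, 0.17),
        "CO": (461.32, 584.53, 1309.90, 0.25),
        "PTF": (903.71, 618.70, 1046.00, 0.24),
        "SFF": (636.58, 374.52, 755.11, 0.21),
        "BN": (267.23, 384.72, 633.99, 0.30),
        "BW": (270.58, 315.13, 584.43, 0.27),
        "BUF": (457.33, 477.58, 1124.10, 0.23),
        "CF": (294.29, 240.99, 692.73, 0.20),
        "Straight": (342.65, 288.71, 940.42, 0.18),
        "Sloping": (411.64, 368.72, 906.70, 0.22),
    }


def records_from_counts(counts: dict[str, tuple[int, int, int]]) -> pd.DataFrame:
    """Record table whose per-trait class counts match the given triples."""
    width = max(sum(c) for c in counts.values())
    data: dict[str, list] = {t: [] for t in counts}
    for t, (n0, n1, n2) in counts.items():
        col = [0.0] * n0 + [1.0] * n1 + [2.0] * n2
        col += [np.nan] * (width - len(col))
        data[t] = col
    df = pd.DataFrame(data)
    df.insert(0, "animal", [f"A{i:04d}" for i in range(width)])
    df.insert(0, "record_id", np.arange(width))
    for f in FACTORS:
        df[f] = 1
    return df
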