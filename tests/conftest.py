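import numpy as np
import pandas as pd
import pytest

from thermoresil import Pedigree


def tabular_a(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix by the recursive tabular method.

    Independent oracle: uses only the sorted parent pointers, never the
    package's Henderson/Meuwissen-Luo code paths.
    """
    n = len(ped)
    a = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        for j in range(i):
            val = 0.0
            if s >= 0:
                val += 0.5 * a[j, s]
            if d >= 0:
                val += 0.5 * a[j, d]
            a[i, j] = a[j, i] = val
        a[i, i] = 1.0 + (0.5 * a[s, d] if s >= 0 and d >= 0 else 0.0)
    return a


def random_pedigree(rng: np.random.Generator, n: int = 25) -> Pedigree:
    """Random acyclic pedigree with unknown parents and some inbreeding."""
    trios = []
    for i in range(n):
        if i < 4 or rng.random() < 0.2:
            trios.append((f"x{i}", None, None))
        else:
            s = f"x{rng.integers(0, i)}"
            d = f"x{rng.integers(0, i)}"
            if d == s:  # self-mating never occurs in sheep
                d = None
            trios.append((f"x{i}", s, rng.choice([d, None])
                          if rng.random() < 0.15 else d))
    return Pedigree.from_records(trios)


@pytest.fixture
def trio_pedigree():
    return Pedigree.from_records(
        [("sire", None, None), ("dam", None, None), ("kid", "sire", "dam")])


@pytest.fixture
def toy_records():
    """Two animals, one lactation each, deterministic yields."""
    rows = []
    for animal, lamb in [("e1", "2015-10-01"), ("e2", "2016-01-15")]:
        for k, dim in enumerate([42, 72, 102, 132]):
            rows.append({
                "animal_id": animal, "flock_id": "F1",
                "lambing_date": lamb,
                "test_date": (pd.Timestamp(lamb)
                              + pd.Timedelta(days=dim)).date().isoformat(),
                "lactation_number": 1, "dim": dim,
                "milk_kg": 2.0 - 0.2 * k,
            })
    return pd.DataFrame(rows)
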