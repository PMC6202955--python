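import numpy as np
import pandas as pd
import pytest

from nomtrait.matrix import TraitDef, TraitMatrix


def make_tm(columns: dict[str, list[str]], categories: dict[str, list[str]] | None = None,
            ids=None) -> TraitMatrix:
    """Small literal trait matrix; category sets default to sorted observed labels."""
    n = len(next(iter(columns.values())))
    ids = ids if ids is not None else [f"s{i}" for i in range(n)]
    df = pd.DataFrame(columns, index=ids, dtype=object)
    cb = {}
    for t, vals in columns.items():
        if categories and t in categories:
            cats = categories[t]
        else:
            cats = sorted({v for v in vals if not pd.isna(v)})
        cb[t] = TraitDef(list(cats), "morphology")
    return TraitMatrix(df, cb)


def random_tm(rng: np.random.Generator, n: int, m: int, kmax: int = 4) -> TraitMatrix:
    """Random complete nominal matrix with K_c drawn in 2..kmax."""
    cols = {}
    cats = {}
    for j in range(m):
        K = int(rng.integers(2, kmax + 1))
        labels = [f"c{u}" for u in range(K)]
        cols[f"t{j}"] = list(np.array(labels, dtype=object)[rng.integers(0, K, size=n)])
        cats[f"t{j}"] = labels
    return make_tm(cols, cats)


@pytest.fixture
def worked_matrix() -> TraitMatrix:
    """The 4-object, 1-trait matrix [A, A, B, C] used for hand-checked indices."""
    return make_tm({"t": ["A", "A", "B", "C"]}, {"t": ["A", "B", "C"]})
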