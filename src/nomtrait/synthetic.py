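"""Synthetic nominal trait matrices with planted functional-group structure.

Real species-trait tables for community-ecology clustering studies are rarely
deposited, so the test surface of this package runs on generated matrices that
emulate their shape: on the order of a hundred species, ~20 nominal traits
with 2-7 categories each, and missingness up to ~23% per trait.

The generative model: species are split into ``n_groups`` balanced groups;
each group has a *preferred* category per trait, assigned cyclically across
traits so that no single trait identifies every group (mimicking trait
redundancy across diet/habitat/morphology functions).  A cell takes its
group's preferred category with probability ``theta`` and any other category
uniformly with the remaining mass.  ``theta = 1/K_c`` is exactly the uniform
(no-signal) distribution; ``theta = 1`` makes every group's rows identical.

MCAR amputation deletes a fixed number of cells uniformly at random and keeps
the true values in a mask, which is how imputation accuracy is benchmarked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import TraitDef, TraitMatrix

__all__ = ["SyntheticSpec", "generate", "ampute_mcar", "default_spec"]

# Category counts of the published 21-trait catalogue, padded with one
# 4-category trait to the 22-trait working matrix the study describes.
CATALOGUE_K = [5, 4, 4, 5, 4, 6, 3, 7, 2, 5, 3, 7, 4, 3, 2, 4, 4, 4, 3, 3, 4, 4]


@dataclass
class SyntheticSpec:
    """Parameters of the planted-partition generator.

    theta
        Within-group concentration in [0, 1]: probability mass on the group's
        preferred category, remainder spread uniformly over the others.
        theta = 1/K_c carries no group signal for a K_c-category trait.
    """

    n_species: int = 116
    n_groups: int = 3
    categories: list[int] = field(default_factory=lambda: list(CATALOGUE_K))
    theta: float = 0.9
    missing: float = 0.0
    seed: int = 0

    @property
    def n_traits(self) -> int:
        return len(self.categories)

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError(f"theta must be in [0, 1], got {self.theta}")
        if not 0.0 <= self.missing <= 0.45:
            raise ValueError(f"missing fraction must be in [0, 0.45], got {self.missing}")
        if any(k < 2 for k in self.categories):
            raise ValueError("every trait needs at least 2 categories")
        if not 1 <= self.n_groups <= self.n_species:
            raise ValueError("need 1 <= n_groups <= n_species")


def default_spec(**overrides) -> SyntheticSpec:
    """The default study-shaped fixture: 116 species, 22 traits, 3 groups."""
    return SyntheticSpec(**overrides)


def generate(spec: SyntheticSpec) -> tuple[TraitMatrix, np.ndarray]:
    """Draw a matrix from the planted-partition model.

    Returns the matrix and the true group label per species (1..n_groups).
    Groups are balanced up to remainder; all randomness flows from
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n, m, g = spec.n_species, spec.n_traits, spec.n_groups
    truth = np.arange(n) % g + 1  # balanced assignment, deterministic
    data = {}
    codebook = {}
    for c, K in enumerate(spec.categories):
        cats = [f"c{u + 1}" for u in range(K)]
        name = f"t{c + 1:02d}"
        codebook[name] = TraitDef(cats, "morphology")
        # cyclic preferred category: group j prefers (j + c) mod K
        probs = np.full((g, K), (1.0 - spec.theta) / (K - 1))
        for j in range(g):
            probs[j, (j + c) % K] = spec.theta
        u = rng.random(n)
        cum = np.cumsum(probs[truth - 1], axis=1)
        idx = (u[:, None] > cum).sum(axis=1)
        data[name] = np.array(cats, dtype=object)[idx]
    ids = [f"sp{i + 1:03d}" for i in range(n)]
    tm = TraitMatrix(pd.DataFrame(data, index=ids), codebook)
    if spec.missing > 0:
        tm, _ = ampute_mcar(tm, spec.missing, seed=int(rng.integers(2**31)))
    return tm, truth


def ampute_mcar(
    tm: TraitMatrix, proportion: float, seed: int, allow_noop: bool = False
) -> tuple[TraitMatrix, pd.DataFrame]:
    """Delete cells completely at random; return the amputed matrix and a mask.

    Exactly ``round(proportion * n * m)`` cells are set missing, uniformly
    without replacement.  The mask is a DataFrame holding the true value at
    each deleted cell and NaN elsewhere, so an imputation can be scored
    against it.  Deleting a column entirely is an error (the imputers need at
    least one observed value per trait), as is a proportion so small that no
    cell would be deleted, unless ``allow_noop``.
    """
    if not 0.0 < proportion <= 0.45:
        raise ValueError(f"proportion must be in (0, 0.45], got {proportion}")
    if tm.missing_mask().any():
        raise ValueError("matrix already has missing cells")
    rng = np.random.default_rng(seed)
    n, m = tm.n, tm.m
    n_del = int(round(proportion * n * m))
    if n_del == 0:
        if allow_noop:
            empty = pd.DataFrame(np.nan, index=tm.df.index,
                                 columns=tm.df.columns, dtype=object)
            return tm.copy(), empty
        raise ValueError(f"proportion {proportion} deletes zero cells on {n}x{m}")
    flat = rng.choice(n * m, size=n_del, replace=False)
    rows, cols = np.unravel_index(flat, (n, m))
    per_col = np.bincount(cols, minlength=m)
    emptied = [tm.trait_names[j] for j in range(m) if per_col[j] == n]
    if emptied:
        raise ValueError(f"amputation would empty column(s) {emptied}")
    df = tm.df.copy()
    mask = pd.DataFrame(np.nan, index=df.index, columns=df.columns, dtype=object)
    for i, j in zip(rows, cols):
        mask.iat[i, j] = df.iat[i, j]
        df.iat[i, j] = np.nan
    return tm.with_values(df), mask
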