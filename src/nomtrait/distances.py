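"""Pairwise dissimilarity measures for nominal data.

Euclidean-style distances assume an ordering of values that nominal traits do
not have, so categorical clustering relies on per-attribute similarity
functions that score a match/mismatch on each trait and average over traits.
Five measures are provided, spanning the main weighting philosophies:

``sm``
    Simple matching: 1 on match, 0 on mismatch (the nominal part of Gower's
    coefficient).
``eskin``
    Mismatches are cheaper on traits with more categories: mismatch
    similarity K^2 / (K^2 + 2) for a K-category trait.
``iof``
    Inverse occurrence frequency: a mismatch between two frequent categories
    is penalized more; mismatch similarity 1 / (1 + ln f(x) * ln f(y)) with
    absolute counts f.
``goodall``
    A match on a rare category counts more: match similarity 1 - p2(x) where
    p2 is the probability two random objects both show the category; mismatch
    similarity 0.
``lin``
    Information-theoretic: per-trait score 2 ln p(x) on match and
    2 ln(p(x) + p(y)) on mismatch, normalized by sum_c ln p(x_c) + ln p(y_c).

All frequencies are recomputed from whatever matrix is passed — a bootstrap
resample is a self-contained dataset.  Dissimilarity = 1 - similarity by
default; the reciprocal transform 1/S - 1 is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .matrix import TraitMatrix

__all__ = [
    "MEASURES",
    "FrequencyTable",
    "DissimilarityMatrix",
    "build_frequency_table",
    "dissimilarity",
]

MEASURES = ("sm", "eskin", "iof", "goodall", "lin")


@dataclass
class FrequencyTable:
    """Per-trait category counts of the matrix being clustered.

    counts[c][u] is the absolute frequency f_c(u) of category u (codebook
    order) in trait c; ``p`` holds relative frequencies f/n and ``p2`` the
    pair estimate f(f-1) / (n(n-1)) — the probability that two objects drawn
    without replacement agree on that category.
    """

    n: int
    trait_names: list[str]
    counts: list[np.ndarray]

    @property
    def p(self) -> list[np.ndarray]:
        return [f / self.n for f in self.counts]

    @property
    def p2(self) -> list[np.ndarray]:
        denom = self.n * (self.n - 1)
        return [f * (f - 1) / denom for f in self.counts]


@dataclass
class DissimilarityMatrix:
    """Symmetric n x n dissimilarities with provenance."""

    values: np.ndarray
    ids: list
    measure: str
    frequency_table: FrequencyTable | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle vector in scipy ``pdist`` order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def build_frequency_table(tm: TraitMatrix) -> FrequencyTable:
    if not tm.is_complete():
        raise ValueError("frequency table requires a complete matrix (impute first)")
    codes = tm.codes()
    counts = [
        np.bincount(codes[:, j], minlength=len(tm.categories(t))).astype(float)
        for j, t in enumerate(tm.trait_names)
    ]
    return FrequencyTable(tm.n, tm.trait_names, counts)


def _per_trait_similarity(
    codes_j: np.ndarray, measure: str, K: int, f: np.ndarray, n: int
) -> np.ndarray:
    """n x n per-attribute similarity for one trait (Lin handled separately)."""
    match = codes_j[:, None] == codes_j[None, :]
    if measure == "sm":
        return match.astype(float)
    if measure == "eskin":
        mis = K * K / (K * K + 2.0)
        return np.where(match, 1.0, mis)
    if measure == "iof":
        lf = np.log(f[codes_j])
        return np.where(match, 1.0, 1.0 / (1.0 + lf[:, None] * lf[None, :]))
    if measure == "goodall":
        p2 = f * (f - 1) / (n * (n - 1))
        sim_match = 1.0 - p2[codes_j]  # matching cells share the category
        return np.where(match, sim_match[:, None], 0.0)
    raise ValueError(f"unknown measure {measure!r}")


def dissimilarity(
    tm: TraitMatrix,
    measure: str,
    ft: FrequencyTable | None = None,
    transform: str = "one_minus",
) -> DissimilarityMatrix:
    """Pairwise dissimilarity matrix under one of the five nominal measures.

    Parameters
    ----------
    tm
        Complete trait matrix.
    measure
        One of ``sm``, ``eskin``, ``iof``, ``goodall``, ``lin``.
    ft
        Frequency table; recomputed from ``tm`` when omitted.  Pass the table
        explicitly only if it was built from this same matrix.
    transform
        ``"one_minus"`` (default): d = 1 - S; ``"reciprocal"``: d = 1/S - 1.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    if transform not in ("one_minus", "reciprocal"):
        raise ValueError(f"unknown transform {transform!r}")
    if ft is None:
        ft = build_frequency_table(tm)
    codes = tm.codes()
    if (codes < 0).any():
        raise ValueError("matrix has missing cells; impute before computing distances")
    n, m = codes.shape

    if measure == "lin":
        S = _lin_similarity(codes, ft)
    else:
        acc = np.zeros((n, n))
        for j, trait in enumerate(tm.trait_names):
            K = len(tm.categories(trait))
            acc += _per_trait_similarity(codes[:, j], measure, K, ft.counts[j], ft.n)
        S = acc / m

    if transform == "one_minus":
        D = 1.0 - S
    else:
        with np.errstate(divide="ignore"):
            D = np.where(S > 0, 1.0 / np.maximum(S, 1e-300) - 1.0, np.inf)
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    D = (D + D.T) / 2.0  # enforce exact symmetry against fp noise
    return DissimilarityMatrix(D, tm.species_ids, measure, ft)


def _lin_similarity(codes: np.ndarray, ft: FrequencyTable) -> np.ndarray:
    n, m = codes.shape
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for j in range(m):
        p = ft.counts[j] / ft.n
        logp = np.log(p[codes[:, j]])
        match = codes[:, j][:, None] == codes[:, j][None, :]
        px = p[codes[:, j]]
        with np.errstate(divide="ignore"):
            s = np.where(match, 2.0 * logp[:, None],
                         2.0 * np.log(px[:, None] + px[None, :]))
        num += s
        den += logp[:, None] + logp[None, :]
    out = np.ones((n, n))
    nz = den != 0
    out[nz] = num[nz] / den[nz]
    if (~nz).any():
        warnings.warn(
            "Lin similarity undefined for pairs with all single-category traits; "
            "dissimilarity set to 0 for those pairs",
            RuntimeWarning,
        )
    return out
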