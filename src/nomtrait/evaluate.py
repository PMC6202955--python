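"""Internal validity indices for partitions of nominal data.

With no ground-truth groups, clusterings of categorical matrices are judged
internally.  Compactness is the within-cluster entropy coefficient

    WCE(k) = sum_g n_g/(n m) * sum_c ( -sum_u (n_gcu/n_g) ln(n_gcu/n_g) )

a size-weighted mean per-cluster, per-trait Shannon entropy (0 = every
cluster single-valued on every trait).  Separation is the entropy-based
pseudo-F

    PSFE(k) = (n - k) [nWCE(1) - nWCE(k)] / ((k - 1) nWCE(k)),  nWCE = n * WCE

maximized over k to choose the number of groups.  Because WCE only falls as
k grows, its per-step decrease Delta WCE(k) = WCE(k-1) - WCE(k) is the more
informative display.  Gini twins replace the entropy term with the impurity
1 - sum_u p^2.  Agreement between two partitions is the chance-corrected
(Hubert-Arabie) adjusted Rand index.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .cluster import Dendrogram, Partition, cut_tree
from .matrix import TraitMatrix

__all__ = [
    "wce",
    "gini_within",
    "psfe",
    "pseudo_f_from_within",
    "gini_indices",
    "delta_wce",
    "select_k",
    "adjusted_rand",
    "evaluate_cuts",
    "evaluate_grid",
]


def _cluster_trait_counts(codes: np.ndarray, labels: np.ndarray, K: list[int]):
    """Yield (n_g, per-category count arrays per trait) for each cluster."""
    for g in np.unique(labels):
        sub = codes[labels == g]
        yield len(sub), [np.bincount(sub[:, c], minlength=K[c]) for c in range(len(K))]


def _check_alignment(tm: TraitMatrix, part: Partition) -> np.ndarray:
    if list(part.ids) != list(tm.species_ids):
        raise ValueError("partition ids do not match the trait matrix")
    return part.labels


def wce(tm: TraitMatrix, part: Partition) -> float:
    """Within-cluster entropy coefficient (compactness; lower is tighter)."""
    labels = _check_alignment(tm, part)
    codes = tm.codes()
    if (codes < 0).any():
        raise ValueError("matrix has missing cells")
    n, m = codes.shape
    K = tm.n_categories()
    total = 0.0
    for n_g, counts in _cluster_trait_counts(codes, labels, K):
        ent = 0.0
        for cnt in counts:
            p = cnt[cnt > 0] / n_g
            ent += float(-(p * np.log(p)).sum())  # 0 ln 0 = 0 by omission
        total += n_g / (n * m) * ent
    return total


def gini_within(tm: TraitMatrix, part: Partition) -> float:
    """Gini-impurity twin of WCE (1 - sum p^2 replaces Shannon entropy)."""
    labels = _check_alignment(tm, part)
    codes = tm.codes()
    n, m = codes.shape
    K = tm.n_categories()
    total = 0.0
    for n_g, counts in _cluster_trait_counts(codes, labels, K):
        imp = sum(1.0 - float(((cnt / n_g) ** 2).sum()) for cnt in counts)
        total += n_g / (n * m) * imp
    return total


def pseudo_f_from_within(w1: float, wk: float, n: int, k: int) -> float:
    """Pseudo-F from a whole-data and a k-cluster within-variability value.

    The n in nW cancels, so the statistic is (n-k)(W(1) - W(k)) / ((k-1) W(k)).
    W(k) = 0 with structure present (W(1) > 0) means perfect clusters: +inf,
    ranked above every finite value.  W(1) = 0 (no variability at all) makes
    the ratio meaningless: NaN.
    """
    if k < 2:
        raise ValueError("pseudo-F requires k >= 2")
    if w1 == 0.0:
        return float("nan")
    if wk == 0.0:
        return float("inf")
    return (n - k) * (w1 - wk) / ((k - 1) * wk)


def psfe(tm: TraitMatrix, cuts: dict[int, Partition]) -> dict[int, float]:
    """Entropy pseudo-F for each k >= 2 cut; requires the k = 1 baseline.

    ``cuts`` maps k to the partition at that k and must include k = 1
    (or it is derived as the all-in-one partition).
    """
    n = tm.n
    if 1 in cuts:
        w1 = wce(tm, cuts[1])
    else:
        w1 = wce(tm, Partition(tm.species_ids, np.ones(n, dtype=int)))
    return {
        k: pseudo_f_from_within(w1, wce(tm, p), n, k)
        for k, p in sorted(cuts.items())
        if k >= 2
    }


def gini_indices(tm: TraitMatrix, part: Partition) -> tuple[float, float]:
    """(within-cluster Gini variability, Gini pseudo-F) for one partition."""
    gk = gini_within(tm, part)
    g1 = gini_within(tm, Partition(tm.species_ids, np.ones(tm.n, dtype=int)))
    if part.k < 2:
        return gk, float("nan")
    return gk, pseudo_f_from_within(g1, gk, tm.n, part.k)


def delta_wce(wce_by_k: dict[int, float]) -> dict[int, float]:
    """Per-step WCE decrease Delta(k) = WCE(k-1) - WCE(k), k >= 2.

    Requires consecutive k values (nested cuts from one dendrogram).
    """
    ks = sorted(wce_by_k)
    for a, b in zip(ks, ks[1:]):
        if b != a + 1:
            raise ValueError(f"non-consecutive k values: {ks}")
    return {k: wce_by_k[k - 1] - wce_by_k[k] for k in ks[1:]}


def select_k(psfe_by_k: dict[int, float], k_range=None) -> int:
    """argmax of pseudo-F over the k grid; ties -> smallest k.

    +inf ("perfect clusters") outranks every finite value; NaN entries are
    excluded.  All-NaN is an error.
    """
    if k_range is None:
        k_range = sorted(psfe_by_k)
    cand = [(k, psfe_by_k[k]) for k in k_range
            if k in psfe_by_k and not np.isnan(psfe_by_k[k])]
    if not cand:
        raise ValueError("pseudo-F undefined for every k in range")
    best_k, best_v = cand[0]
    for k, v in cand[1:]:
        if v > best_v:
            best_k, best_v = k, v
    return best_k


def adjusted_rand(p1: Partition, p2: Partition) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions (1 = identical)."""
    if sorted(map(str, p1.ids)) != sorted(map(str, p2.ids)):
        raise ValueError("partitions cover different object sets")
    if list(p1.ids) != list(p2.ids):
        lut = {i: lab for i, lab in zip(p2.ids, p2.labels)}
        l2 = np.array([lut[i] for i in p1.ids])
    else:
        l2 = p2.labels
    return float(adjusted_rand_score(p1.labels, l2))


def evaluate_cuts(tm: TraitMatrix, dg: Dendrogram, k_range=range(2, 11)) -> pd.DataFrame:
    """All indices for the nested cuts of one dendrogram over a k grid.

    Columns: k, wce, psfe, gini_w, gini_psf, delta_wce, optimal (PSFE argmax).
    """
    ks = sorted(set(k_range))
    kmax = min(max(ks), tm.n)
    ks = [k for k in ks if 2 <= k <= kmax]
    cuts = {1: cut_tree(dg, 1)}
    cuts.update({k: cut_tree(dg, k) for k in range(2, max(ks) + 1)})
    w = {k: wce(tm, p) for k, p in cuts.items()}
    g = {k: gini_within(tm, p) for k, p in cuts.items()}
    n = tm.n
    pf = {k: pseudo_f_from_within(w[1], w[k], n, k) for k in w if k >= 2}
    pg = {k: pseudo_f_from_within(g[1], g[k], n, k) for k in g if k >= 2}
    dw = delta_wce(w)
    k_best = None
    try:
        k_best = select_k(pf, ks)
    except ValueError:
        pass
    rows = [
        {"k": k, "wce": w[k], "psfe": pf[k], "gini_w": g[k], "gini_psf": pg[k],
         "delta_wce": dw[k], "optimal": k == k_best}
        for k in ks
    ]
    return pd.DataFrame(rows)


def evaluate_grid(tm: TraitMatrix, measures, linkages, k_range=range(2, 11)) -> pd.DataFrame:
    """Index table over the full measure x linkage x k grid.

    The classic study design is 5 measures x 3 linkages x k in 2..10; the
    optimal flag marks the PSFE-selected k within each (measure, linkage).
    """
    from .cluster import hierarchical_cluster
    from .distances import dissimilarity

    frames = []
    for meas in measures:
        d = dissimilarity(tm, meas)
        for link in linkages:
            dg = hierarchical_cluster(d, link)
            sub = evaluate_cuts(tm, dg, k_range)
            sub.insert(0, "linkage", link)
            sub.insert(0, "measure", meas)
            frames.append(sub)
    return pd.concat(frames, ignore_index=True)
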