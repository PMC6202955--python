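"""Independent brute-force reference implementations used only by the tests.

Each oracle recomputes a quantity by the most direct route available —
enumerating cross-pairs, medoid sets or object pairs — and stays independent
of the package code paths it checks.
"""

from itertools import combinations

import numpy as np


def naive_agglomerate(D: np.ndarray, linkage: str) -> np.ndarray:
    """Direct agglomeration: every step recomputes D(A, B) from the original
    pairwise distances over all cross-pairs (no Lance-Williams recursion).

    Uses the same node numbering and tie rule as the package (leaves 0..n-1,
    merge t creates node n+t; lexicographically lowest id pair wins ties) so
    merge tables are comparable row by row.
    """
    n = D.shape[0]
    members = {i: [i] for i in range(n)}
    active = list(range(n))
    merges = np.zeros((n - 1, 4))
    for t in range(n - 1):
        best, best_d = None, np.inf
        for a, b in combinations(sorted(active), 2):
            cross = [D[x, y] for x in members[a] for y in members[b]]
            if linkage == "single":
                dd = min(cross)
            elif linkage == "complete":
                dd = max(cross)
            else:
                dd = sum(cross) / len(cross)
            if dd < best_d:
                best_d, best = dd, (a, b)
        a, b = best
        new = n + t
        members[new] = members[a] + members[b]
        merges[t] = [a, b, best_d, len(members[new])]
        active = [c for c in active if c not in (a, b)] + [new]
    return merges


def pam_total_cost(D: np.ndarray, medoids) -> float:
    return float(D[:, list(medoids)].min(axis=1).sum())


def pam_brute_force(D: np.ndarray, k: int):
    """Globally optimal medoid set by exhaustive enumeration (tiny n only)."""
    n = D.shape[0]
    best, best_cost = None, np.inf
    for med in combinations(range(n), k):
        cost = pam_total_cost(D, med)
        if cost < best_cost:
            best_cost, best = cost, med
    return best, best_cost


def ari_pair_counting(labels1, labels2) -> float:
    """Adjusted Rand via explicit counts over all object pairs."""
    labels1, labels2 = np.asarray(labels1), np.asarray(labels2)
    n11 = n00 = n10 = n01 = 0
    for i, j in combinations(range(len(labels1)), 2):
        same1 = labels1[i] == labels1[j]
        same2 = labels2[i] == labels2[j]
        if same1 and same2:
            n11 += 1
        elif same1:
            n10 += 1
        elif same2:
            n01 += 1
        else:
            n00 += 1
    num = 2.0 * (n11 * n00 - n10 * n01)
    den = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    return 1.0 if den == 0 else num / den


def wce_direct(codes: np.ndarray, labels: np.ndarray) -> float:
    """Size-weighted per-cluster per-trait entropy, written out longhand."""
    n, m = codes.shape
    total = 0.0
    for g in np.unique(labels):
        sub = codes[labels == g]
        ng = len(sub)
        for c in range(m):
            for u in np.unique(sub[:, c]):
                p = np.mean(sub[:, c] == u)
                total += ng / (n * m) * (-p * np.log(p))
    return total
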