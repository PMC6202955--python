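"""Agglomerative hierarchical clustering and k-medoids on dissimilarity matrices.

Agglomeration starts from singletons and repeatedly fuses the least dissimilar
pair of clusters under the chosen linkage:

- single:   D(A, B) = min d(x, y) over x in A, y in B
- complete: D(A, B) = max d(x, y)
- average:  D(A, B) = (1 / n_A n_B) * sum d(x, y)

The implementation is the direct O(n^3) scheme with Lance-Williams updates —
at the ~100-species scale of trait matrices nothing faster is warranted, and
writing it out lets the merge order be bit-reproducible under a fixed tie
rule: among pairs at the minimal distance, the pair with the lowest (smaller,
larger) cluster ids merges first.  scipy's linkage is used in the test suite
as an independent cross-check, not here.

PAM (partitioning around medoids) is the k-medoids used for bootstrap
stability: BUILD greedily seeds k medoids, SWAP exchanges medoids with
non-medoids while the total dissimilarity of objects to their nearest medoid
decreases.  Both phases are deterministic, so PAM needs no seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distances import DissimilarityMatrix

__all__ = [
    "LINKAGES",
    "Dendrogram",
    "Partition",
    "hierarchical_cluster",
    "cut_tree",
    "pam",
]

LINKAGES = ("single", "complete", "average")


@dataclass
class Partition:
    """Assignment of n objects to clusters labelled 1..k, all nonempty.

    ``medoids`` (positional indices) is set when the partition came from
    k-medoids; None otherwise.
    """

    ids: list
    labels: np.ndarray  # int, 1..k
    medoids: np.ndarray | None = None
    k: int = field(init=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.labels) != len(self.ids):
            raise ValueError("one label per object required")
        present = np.unique(self.labels)
        self.k = len(present)
        if not np.array_equal(present, np.arange(1, self.k + 1)):
            raise ValueError(f"labels must be exactly 1..k nonempty, got {present}")

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]

    def members(self, g: int) -> list:
        return [i for i, lab in zip(self.ids, self.labels) if lab == g]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"id": self.ids, "cluster": self.labels})


@dataclass
class Dendrogram:
    """Full agglomeration history in scipy linkage-matrix layout.

    Row t of ``merges`` is [left, right, height, size]: node ids < n are
    leaves, node n + t is created by merge t.  Heights are the inter-cluster
    dissimilarity D(A, B) at fusion and are non-decreasing for single,
    complete and average linkage.
    """

    leaf_ids: list
    merges: np.ndarray  # (n-1, 4)
    linkage: str
    measure: str = ""

    @property
    def n(self) -> int:
        return len(self.leaf_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_scipy(self) -> np.ndarray:
        return self.merges.copy()

    def to_merge_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.merges, columns=["left", "right", "height", "size"]
        ).astype({"left": int, "right": int, "size": int})

    def cut(self, k: int) -> Partition:
        return cut_tree(self, k)

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height - child height."""
        n = self.n
        height = {i: 0.0 for i in range(n)}
        node = {i: str(self.leaf_ids[i]) for i in range(n)}
        for t, (a, b, h, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            la = max(h - height[a], 0.0)
            lb = max(h - height[b], 0.0)
            node[n + t] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
            height[n + t] = h
        return node[n + len(self.merges) - 1] + ";"


def hierarchical_cluster(d: DissimilarityMatrix, linkage: str) -> Dendrogram:
    """Agglomerate a dissimilarity matrix under single/complete/average linkage."""
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    D = np.asarray(d.values, dtype=float).copy()
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    size = {i: 1 for i in range(n)}
    active = list(range(n))  # kept sorted by cluster id
    dist = {}  # (lo_id, hi_id) -> D(A, B)
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = D[i, j]
    merges = np.zeros((n - 1, 4))
    for t in range(n - 1):
        best = None
        best_d = np.inf
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                key = (active[ai], active[bi])
                dd = dist[key]
                if dd < best_d:  # strict: first (lexicographically lowest) tie wins
                    best_d, best = dd, key
        a, b = best
        new = n + t
        merges[t] = [a, b, best_d, size[a] + size[b]]
        # Lance-Williams update of distances to the fused cluster
        for c in active:
            if c in (a, b):
                continue
            dac = dist[(min(a, c), max(a, c))]
            dbc = dist[(min(b, c), max(b, c))]
            if linkage == "single":
                dnew = min(dac, dbc)
            elif linkage == "complete":
                dnew = max(dac, dbc)
            else:
                dnew = (size[a] * dac + size[b] * dbc) / (size[a] + size[b])
            dist[(c, new)] = dnew
        size[new] = size[a] + size[b]
        active = [c for c in active if c not in (a, b)] + [new]
    return Dendrogram(list(d.ids), merges, linkage, d.measure)


def cut_tree(dg: Dendrogram, k: int) -> Partition:
    """Partition into k clusters by undoing the last k - 1 merges.

    Cluster labels are 1..k in order of each cluster's smallest leaf index.
    """
    n = dg.n
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in range(n - k):
        a, b = int(dg.merges[t, 0]), int(dg.merges[t, 1])
        parent[find(a)] = parent[find(b)] = n + t
    roots = [find(i) for i in range(n)]
    order: dict[int, int] = {}
    labels = np.zeros(n, dtype=np.int64)
    for i, r in enumerate(roots):
        if r not in order:
            order[r] = len(order) + 1
        labels[i] = order[r]
    return Partition(list(dg.leaf_ids), labels)


def pam(d: DissimilarityMatrix, k: int, seed: int | None = None) -> Partition:
    """k-medoids by BUILD + SWAP on a precomputed dissimilarity matrix.

    Deterministic given the matrix: BUILD is greedy and SWAP applies the best
    improving exchange (ties broken by lowest indices) until a local optimum.
    ``seed`` is accepted for interface symmetry; the default algorithm does
    not use randomness.
    """
    D = np.asarray(d.values, dtype=float)
    n = D.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"k must be in [2, {n - 1}], got {k}")

    # BUILD: first medoid minimizes total distance; then greedy additions.
    medoids = [int(np.argmin(D.sum(axis=0)))]
    dn = D[:, medoids[0]].copy()  # distance to nearest chosen medoid
    while len(medoids) < k:
        gains = np.maximum(dn[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        c = int(np.argmax(gains))
        medoids.append(c)
        dn = np.minimum(dn, D[:, c])

    medoids = sorted(medoids)
    while True:
        med = np.array(medoids)
        dmat = D[:, med]  # n x k
        order = np.argsort(dmat, axis=1, kind="stable")
        d1 = dmat[np.arange(n), order[:, 0]]
        d2 = dmat[np.arange(n), order[:, 1]]
        nearest = order[:, 0]
        best_delta, best_swap = 0.0, None
        for mi in range(k):
            # cost to every point if medoid mi is removed and h added
            base = np.where(nearest == mi, d2, d1)
            cand_cost = np.minimum(base[:, None], D).sum(axis=0)
            cur_cost = d1.sum()
            for h in range(n):
                if h in medoids:
                    continue
                delta = cand_cost[h] - cur_cost
                if delta < best_delta - 1e-12:
                    best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        mi, h = best_swap
        medoids[mi] = h
        medoids = sorted(medoids)

    med = np.array(medoids)
    lab_idx = np.argmin(D[:, med], axis=1)
    for j, mm in enumerate(med):  # a medoid always belongs to its own cluster
        lab_idx[mm] = j
    labels = np.zeros(n, dtype=np.int64)
    order_map: dict[int, int] = {}
    for i in range(n):
        g = int(lab_idx[i])
        if g not in order_map:
            order_map[g] = len(order_map) + 1
        labels[i] = order_map[g]
    return Partition(list(d.ids), labels, medoids=med)
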