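"""Hierarchical clustering of patient-medoids on the Hamming metric.

The agglomeration is Ward's method expressed through Lance-Williams
updates, with observation weights equal to the number of patients each
medoid represents, so the tree reflects patient mass rather than medoid
count.  With unit weights the merge heights coincide with
``scipy.cluster.hierarchy.linkage(..., 'ward')``; with integer weights
they coincide with running scipy's Ward on the weight-expanded dataset.

Note Ward's variance interpretation assumes Euclidean geometry; applying
the same recurrence to Hamming distances is the usual approximation for
categorical sequences and is what this module does.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .medoids import meta_feature_matrix

__all__ = ["ClusterModel", "hamming_matrix", "ward_cluster", "cut_tree",
           "leaf_order", "order_by_severity", "silhouette",
           "visualization_matrix"]


def hamming_matrix(sequences: np.ndarray) -> np.ndarray:
    """Pairwise count of differing positions between equal-length sequences."""
    seqs = np.asarray(sequences)
    if seqs.ndim != 2:
        raise ValueError("sequences must form a 2-D (k, T) array of equal lengths")
    k = len(seqs)
    D = np.zeros((k, k), dtype=np.int64)
    for i in range(k):
        D[i, i + 1:] = (seqs[i + 1:] != seqs[i]).sum(axis=1)
    return D + D.T


@dataclass(frozen=True)
class ClusterModel:
    """Result of a weighted Ward agglomeration and its cut."""

    merges: np.ndarray        # (K-1, 4) scipy-style: id_a, id_b, height, new weight
    n_leaves: int
    member_counts: np.ndarray  # (K,) patients per medoid
    n_clusters: int
    labels: np.ndarray        # (K,) medoid -> cluster in 1..C
    silhouette_value: float | None

    @property
    def leaf_order(self) -> np.ndarray:
        return leaf_order(self.merges, self.n_leaves)

    def patient_counts(self) -> np.ndarray:
        """Patients per cluster (index c-1 holds cluster c)."""
        out = np.zeros(self.n_clusters, dtype=int)
        for c in range(1, self.n_clusters + 1):
            out[c - 1] = int(self.member_counts[self.labels == c].sum())
        return out


def _validate_square(dist: np.ndarray) -> np.ndarray:
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    return D


def ward_linkage(dist: np.ndarray, member_counts: np.ndarray | None = None) -> np.ndarray:
    """Weighted Ward agglomeration; returns a scipy-style linkage matrix.

    Works on squared "Ward distances": two weighted singletons i, j start at
    ``2 w_i w_j / (w_i + w_j) * d_ij^2`` and clusters are combined with the
    Lance-Williams Ward recurrence using total member weights as sizes.
    Ties in the minimum merge distance are broken by the smallest (i, j)
    node-id pair.  Heights are the square roots of the Ward distances, so
    unit weights reproduce scipy's ward linkage exactly.
    """
    D = _validate_square(dist)
    K = len(D)
    w = np.ones(K) if member_counts is None else np.asarray(member_counts, dtype=float)
    if len(w) != K or (w <= 0).any():
        raise ValueError("member_counts must be positive and match the matrix size")

    # Squared Ward distances between current clusters.
    W = np.add.outer(w, w)
    d2 = (2.0 * np.outer(w, w) / W) * D ** 2
    np.fill_diagonal(d2, np.inf)

    size = w.copy()
    node_id = np.arange(K)           # current scipy node id per active row
    active = np.ones(K, dtype=bool)
    Z = np.zeros((K - 1, 4))
    d2 = d2.copy()

    for step in range(K - 1):
        M = np.where(active[:, None] & active[None, :], d2, np.inf)
        flat = int(np.argmin(M))     # row-major argmin -> smallest (i, j) on ties
        i, j = divmod(flat, K)
        if i > j:
            i, j = j, i
        h2 = M[i, j]
        a, b = node_id[i], node_id[j]
        if a > b:
            a, b = b, a
        new_size = size[i] + size[j]
        Z[step] = (a, b, np.sqrt(max(h2, 0.0)), new_size)

        # Lance-Williams Ward update into row/col i; retire j.
        others = active.copy()
        others[i] = others[j] = False
        si, sj, sk = size[i], size[j], size[others]
        d2_new = ((si + sk) * d2[i, others] + (sj + sk) * d2[j, others]
                  - sk * h2) / (si + sj + sk)
        d2[i, others] = d2_new
        d2[others, i] = d2_new
        size[i] = new_size
        node_id[i] = K + step
        active[j] = False
        d2[j, :] = np.inf
        d2[:, j] = np.inf
    return Z


def cut_tree(merges: np.ndarray, n_leaves: int, n_clusters: int) -> np.ndarray:
    """Cut the merge tree into ``n_clusters`` groups.

    Labels are 1..C in order of first appearance by leaf index.
    """
    if not (1 <= n_clusters <= n_leaves):
        raise ValueError("n_clusters must be in [1, number of leaves]")
    parent = np.arange(2 * n_leaves - 1)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n_leaves - n_clusters):
        a, b, _, _ = merges[step]
        new = n_leaves + step
        parent[find(int(a))] = new
        parent[find(int(b))] = new

    roots = [find(i) for i in range(n_leaves)]
    labels = np.zeros(n_leaves, dtype=int)
    mapping: dict[int, int] = {}
    for i, r in enumerate(roots):
        if r not in mapping:
            mapping[r] = len(mapping) + 1
        labels[i] = mapping[r]
    return labels


def leaf_order(merges: np.ndarray, n_leaves: int) -> np.ndarray:
    """Left-to-right dendrogram leaf order (same convention as scipy)."""
    order: list[int] = []
    stack = [2 * n_leaves - 2]
    while stack:
        node = stack.pop()
        if node < n_leaves:
            order.append(node)
        else:
            a, b, _, _ = merges[node - n_leaves]
            stack.append(int(b))
            stack.append(int(a))
    return np.asarray(order)


def ward_cluster(dist: np.ndarray, member_counts: np.ndarray | None = None,
                 n_clusters: int = 4) -> ClusterModel:
    """Full weighted Ward clustering of a medoid distance matrix."""
    D = _validate_square(dist)
    K = len(D)
    counts = (np.ones(K, dtype=int) if member_counts is None
              else np.asarray(member_counts))
    Z = ward_linkage(D, counts)
    labels = cut_tree(Z, K, n_clusters)
    sil = None
    if n_clusters > 1:
        try:
            sil = silhouette(D, labels, counts)
        except ValueError:  # singleton-only cut: silhouette undefined
            sil = None
    return ClusterModel(merges=Z, n_leaves=K, member_counts=counts,
                        n_clusters=n_clusters, labels=labels,
                        silhouette_value=sil)


def order_by_severity(model: ClusterModel, patient_sequences: np.ndarray,
                      assignment: np.ndarray,
                      exacerbation_state: int = 1) -> ClusterModel:
    """Relabel clusters so severity is non-decreasing in the label.

    Severity = mean per-patient number of exacerbation episodes; ties are
    broken by mean total hospitalised (non-zero-state) days.
    """
    seqs = np.asarray(patient_sequences)
    F = meta_feature_matrix(seqs)
    episodes = F[:, 3 * (exacerbation_state - 1) + 1]
    hosp_days = (seqs != 0).sum(axis=1)
    patient_cluster = model.labels[np.asarray(assignment)]

    C = model.n_clusters
    keys = []
    for c in range(1, C + 1):
        mask = patient_cluster == c
        if mask.any():
            keys.append((float(episodes[mask].mean()),
                         float(hosp_days[mask].mean()), c))
        else:
            keys.append((np.inf, np.inf, c))
    ranked = sorted(keys)  # lexicographic: episodes, then days, then old label
    relabel = {old: new + 1 for new, (_, _, old) in enumerate(ranked)}
    new_labels = np.asarray([relabel[c] for c in model.labels])
    return dc_replace(model, labels=new_labels)


def silhouette(dist: np.ndarray, labels: np.ndarray,
               member_counts: np.ndarray | None = None) -> float:
    """Weighted mean silhouette over the patients the medoids represent.

    Each medoid stands for ``member_counts`` coincident patients (mutual
    distance zero), so ``a(i)`` uses within-cluster patient mass minus one
    and ``b(i)`` the full mass of the nearest other cluster.
    """
    D = _validate_square(dist)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    w = (np.ones(len(D)) if member_counts is None
         else np.asarray(member_counts, dtype=float))
    cluster_mass = {c: float(w[labels == c].sum()) for c in uniq}
    if all(cluster_mass[c] == 1.0 for c in uniq):
        raise ValueError("silhouette undefined for singleton-only clustering")

    s = np.zeros(len(D))
    for i in range(len(D)):
        c = labels[i]
        within_mass = cluster_mass[c]
        if within_mass <= 1.0:
            s[i] = 0.0  # lone patient: conventional zero
            continue
        a = float(D[i, labels == c] @ w[labels == c]) / (within_mass - 1.0)
        b = min(float(D[i, labels == o] @ w[labels == o]) / cluster_mass[o]
                for o in uniq if o != c)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float((s * w).sum() / w.sum())


def visualization_matrix(model: ClusterModel, medoids: np.ndarray,
                         member_counts: np.ndarray | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Patient-level raster: each medoid row repeated once per member.

    Rows are grouped by cluster label (1..C); within a cluster, medoids
    appear in dendrogram leaf order.  Returns ``(raster, row_clusters)``;
    the raster has exactly one row per represented patient.
    """
    medoids = np.asarray(medoids)
    counts = (model.member_counts if member_counts is None
              else np.asarray(member_counts))
    order = model.leaf_order
    rows, row_clusters = [], []
    for c in range(1, model.n_clusters + 1):
        for m in order:
            if model.labels[m] == c:
                rows.append(np.repeat(medoids[m][None, :], counts[m], axis=0))
                row_clusters.extend([c] * int(counts[m]))
    raster = np.vstack(rows) if rows else np.empty((0, medoids.shape[1]), dtype=medoids.dtype)
    return raster, np.asarray(row_clusters)
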