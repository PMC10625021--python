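"""Compression of daily state sequences to representative patient-medoids.

Sequences are summarised by per-state meta-features (days in state, number
of episodes, recency of last episode), partitioned with K-means on the
standardised features, and each partition is represented by the member
sequence minimising the total Hamming distance to the partition's members.
The homogeneity score measures how faithfully a medoid stands for a
patient: 100 x (1 - hamming/T).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

__all__ = ["MedoidSet", "CompressionError", "meta_features",
           "meta_feature_matrix", "compress", "homogeneity"]


class CompressionError(ValueError):
    pass


@dataclass(frozen=True)
class MedoidSet:
    """K representative sequences plus the patient->medoid assignment."""

    medoids: np.ndarray        # (K, T) medoid sequences
    assignment: np.ndarray     # (n,) medoid index per patient
    member_counts: np.ndarray  # (K,) patients per medoid
    homogeneity: np.ndarray    # (n,) per-patient score in [0, 100]

    @property
    def k(self) -> int:
        return len(self.medoids)

    @property
    def mean_homogeneity(self) -> float:
        return float(self.homogeneity.mean())

    @property
    def sd_homogeneity(self) -> float:
        return float(self.homogeneity.std(ddof=1)) if len(self.homogeneity) > 1 else 0.0

    def __post_init__(self) -> None:
        if int(self.member_counts.sum()) != len(self.assignment):
            raise ValueError("member counts must sum to the number of patients")
        if (self.member_counts < 1).any():
            raise ValueError("every medoid must represent at least one patient")


def meta_features(seq: np.ndarray, n_states: int | None = None) -> np.ndarray:
    """Per-state summary of one sequence.

    For each non-none state ``s`` (codes 1..S-1) returns three numbers:
    total days spent in ``s``, number of episodes (maximal runs) of ``s``,
    and the day offset of the last day in ``s`` (in ``[-T, -1]``, or the
    sentinel ``-T - 1`` when the state never occurs).
    """
    seq = np.asarray(seq)
    T = len(seq)
    S = int(n_states if n_states is not None else max(int(seq.max(initial=0)) + 1, 2))
    out = np.empty(3 * (S - 1), dtype=float)
    for s in range(1, S):
        mask = seq == s
        days = int(mask.sum())
        if days:
            starts = mask & ~np.concatenate(([False], mask[:-1]))
            episodes = int(starts.sum())
            last = int(np.nonzero(mask)[0][-1]) - T  # position t -> day t - T
        else:
            episodes, last = 0, -T - 1
        out[3 * (s - 1):3 * s] = (days, episodes, last)
    return out


def meta_feature_matrix(seqs: np.ndarray, n_states: int | None = None,
                        mode: str = "full") -> np.ndarray:
    """Stack meta-features for a (n, T) sequence matrix.

    ``mode='days_only'`` keeps only the day-count features.
    """
    seqs = np.asarray(seqs)
    S = int(n_states if n_states is not None else max(int(seqs.max(initial=0)) + 1, 2))
    F = np.vstack([meta_features(row, S) for row in seqs])
    if mode == "days_only":
        F = F[:, 0::3]
    elif mode != "full":
        raise ValueError(f"unknown feature mode: {mode!r}")
    return F


def _standardise(F: np.ndarray) -> np.ndarray:
    mu = F.mean(axis=0)
    sd = F.std(axis=0)
    sd[sd == 0] = 1.0
    return (F - mu) / sd


def _pairwise_hamming(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # (m, T) vs (k, T) -> (m, k); chunked to bound memory.
    m = len(a)
    out = np.empty((m, len(b)), dtype=np.int64)
    step = max(1, int(2e7 // (max(len(b), 1) * a.shape[1] + 1)))
    for lo in range(0, m, step):
        hi = min(lo + step, m)
        out[lo:hi] = (a[lo:hi, None, :] != b[None, :, :]).sum(axis=2)
    return out


def homogeneity(seq: np.ndarray, medoid: np.ndarray) -> float:
    """100 x (1 - hamming(seq, medoid) / T), in [0, 100]."""
    seq = np.asarray(seq)
    medoid = np.asarray(medoid)
    if seq.shape != medoid.shape:
        raise ValueError(f"length mismatch: {seq.shape} vs {medoid.shape}")
    return 100.0 * (1.0 - float((seq != medoid).sum()) / len(seq))


def compress(sequences: np.ndarray, k: int, n_init: int = 10,
             rng_seed: int = 0, feature_mode: str = "full") -> MedoidSet:
    """Compress n sequences into ``k`` patient-medoids.

    Identical sequences are pooled before clustering; K-means (Euclidean,
    standardised meta-features, multiplicity sample weights, best of
    ``n_init`` restarts) partitions the distinct sequences, and each
    partition's medoid is its distance-minimising member.  Deterministic
    given ``rng_seed``.
    """
    seqs = np.asarray(sequences)
    if seqs.ndim != 2:
        raise CompressionError("sequences must be a 2-D (n, T) array")
    n = len(seqs)
    uniq, inverse, counts = np.unique(seqs, axis=0, return_inverse=True,
                                      return_counts=True)
    n_uniq = len(uniq)
    if not (1 <= k <= n_uniq):
        raise CompressionError(
            f"k must be in [1, number of distinct sequences]; got k={k}, "
            f"distinct={n_uniq}")

    if k == n_uniq:
        part_labels = np.arange(n_uniq)
    elif k == 1:
        part_labels = np.zeros(n_uniq, dtype=int)
    else:
        F = _standardise(meta_feature_matrix(uniq, mode=feature_mode))
        km = KMeans(n_clusters=k, n_init=n_init, random_state=rng_seed)
        part_labels = km.fit_predict(F, sample_weight=counts.astype(float))
        part_labels = _fix_empty_partitions(part_labels, F, k)

    medoid_rows = np.empty(k, dtype=int)
    for c in range(k):
        members = np.flatnonzero(part_labels == c)
        D = _pairwise_hamming(uniq[members], uniq[members])
        cost = D @ counts[members]
        medoid_rows[c] = members[int(np.argmin(cost))]  # ties -> lowest index

    medoids = uniq[medoid_rows]
    assignment = part_labels[inverse]
    member_counts = np.bincount(assignment, minlength=k)
    mism = (uniq != medoids[part_labels]).sum(axis=1)
    T = seqs.shape[1]
    homog = (100.0 * (1.0 - mism[inverse] / T)).astype(float)
    return MedoidSet(medoids=medoids, assignment=assignment,
                     member_counts=member_counts, homogeneity=homog)


def _fix_empty_partitions(labels: np.ndarray, F: np.ndarray, k: int) -> np.ndarray:
    """Re-seed any empty partition from the point farthest from its centroid."""
    labels = labels.copy()
    for c in range(k):
        while not (labels == c).any():
            centroids = np.vstack([F[labels == j].mean(axis=0)
                                   if (labels == j).any() else np.zeros(F.shape[1])
                                   for j in range(k)])
            dist = np.linalg.norm(F - centroids[labels], axis=1)
            movable = np.flatnonzero(np.bincount(labels, minlength=k)[labels] > 1)
            far = movable[int(np.argmax(dist[movable]))]
            labels[far] = c
    return labels
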