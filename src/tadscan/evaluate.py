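"""Scoring detected boundaries and hierarchies against ground truth.

TPR is the fraction of true boundaries recovered, FDR the fraction of
detections that match no true boundary (both after one-to-one matching
within a bin tolerance), and ``K̂ - K`` the signed error in the boundary
count.  Hierarchies are compared level by level with the Fowlkes-Mallows
index of the flat partitions obtained by cutting the TAD forest at each
order, with a random-relabelling permutation control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .compare import match_positions
from .detect import TADNode

__all__ = [
    "EvalReport",
    "tpr_fdr",
    "k_diff",
    "hierarchy_to_partition",
    "fowlkes_mallows",
    "relabel_control",
]


@dataclass
class EvalReport:
    tpr: float
    fdr: float
    k_diff: float
    tolerance: int
    b_k: dict[int, float] = field(default_factory=dict)
    b_k_control: dict[int, float] = field(default_factory=dict)


def tpr_fdr(pred, truth, tol: int = 0) -> tuple[float, float]:
    """True-positive rate and false-discovery rate at matching tolerance
    ``tol`` (one-to-one greedy matching by ascending distance).

    ``tpr = 1`` for empty truth and ``fdr = 0`` for empty predictions, by
    convention.
    """
    pred = list(pred)
    truth = list(truth)
    pairs, _, _ = match_positions(pred, truth, tol=tol)
    tpr = len(pairs) / len(truth) if truth else 1.0
    fdr = (len(pred) - len(pairs)) / len(pred) if pred else 0.0
    return tpr, fdr


def k_diff(pred_counts, truth_counts) -> float:
    """Mean over matrices of (number detected - number true)."""
    pred_counts = np.atleast_1d(pred_counts)
    truth_counts = np.atleast_1d(truth_counts)
    if pred_counts.shape != truth_counts.shape:
        raise ValueError("count vectors must have equal length")
    return float(np.mean(pred_counts - truth_counts))


def hierarchy_to_partition(forest: list[TADNode], level: int,
                           n_bins: int | None = None) -> np.ndarray:
    """Flat partition labels from cutting the forest at ``level``.

    Every node of order ``<= level`` with no children of order ``<= level``
    (i.e. leaves of the cut) defines one cluster; shallower leaves stand
    for themselves.
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    if n_bins is None:
        n_bins = max(node.end for node in forest)
    labels = np.full(n_bins, -1, dtype=np.int64)
    nxt = 0
    stack = list(reversed(forest))
    while stack:
        node = stack.pop()
        if node.order == level or not node.children:
            labels[node.start:node.end] = nxt
            nxt += 1
        else:
            stack.extend(reversed(node.children))
    if (labels < 0).any():
        raise ValueError("forest does not tile the bin range")
    return labels


def fowlkes_mallows(labels_a, labels_b) -> float:
    """Fowlkes-Mallows index of two flat partitions of the same objects.

    From the contingency table ``M``: ``T = sum M_ij^2 - n``,
    ``P = sum (row sums)^2 - n``, ``Q = sum (col sums)^2 - n`` and
    ``B = T / sqrt(P Q)`` (0 when ``T = 0``); equals 1 iff the partitions
    coincide, and is invariant to label renaming.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-d and of equal length")
    n = a.size
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    nb = bi.max() + 1
    counts = np.bincount(ai * nb + bi, minlength=(ai.max() + 1) * nb)
    m = counts.reshape(ai.max() + 1, nb)
    t = float((m.astype(np.float64) ** 2).sum() - n)
    p = float((m.sum(axis=1).astype(np.float64) ** 2).sum() - n)
    q = float((m.sum(axis=0).astype(np.float64) ** 2).sum() - n)
    if t == 0.0 or p == 0.0 or q == 0.0:
        return 0.0
    return t / np.sqrt(p * q)


def relabel_control(truth_labels, detected_labels, n_perm: int = 100,
                    seed=None) -> float:
    """Mean Fowlkes-Mallows index between the true partition and randomly
    relabelled detected clusters.

    The detected label vector is permuted across bins, preserving every
    cluster's size while destroying its genomic coherence; the mean index
    over permutations estimates the agreement expected when the two
    clusterings are unrelated (near zero for many small clusters).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    detected = np.asarray(detected_labels)
    vals = [fowlkes_mallows(truth_labels, rng.permutation(detected))
            for _ in range(n_perm)]
    return float(np.mean(vals))
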