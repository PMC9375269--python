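"""The alpha-ladder E-groups and the purity-feature cascade.

Training siRNAs are split into three E-groups by an artificial efficacy cut
``alpha_s = (20 + 5(s-1))%`` for s = 1..11 (20% .. 70%):

* E1 — potent training records (efficacy >= 70%),
* E2 — ineffective with ``alpha_s <= efficacy < 70%``,
* E3 — ineffective with ``efficacy < alpha_s`` (plus any record whose
  efficacy is treated as unknown after being removed from the test set).

For each of the 31 composite encodings C_k and each of the four neighbor
structures t (1 = MG1, 2 = MG2, 3 = Icc1, 4 = Icc2), every record's group
yields a purity triple ``D = (d1, d2, d3)`` — the fractions of E1/E2/E3
members among the E-labeled members of the group.  The triple is binarized to
``(c1, c2)`` with ``c1 = [d1 > d3]`` and ``c2 = [d1 < d3]`` and summed over
the 31 encodings into the aggregate pair ``C^{alpha_s,t}``; the four pairs
concatenate into the 8-vector ``C^{alpha_s}``.

A large second aggregate (many encodings in which the record's neighborhood
is dominated by low-efficacy training records) is the evidence the removal
iteration acts on.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .base_features import N_CK
from .neighbor_structures import Partition

__all__ = [
    "alpha_ladder",
    "stage_index",
    "e_group_labels",
    "assign_e_groups",
    "d_features",
    "compute_d",
    "binarize",
    "binarize_d",
    "aggregate_c",
    "c_alpha_concat",
    "T_METHODS",
]

#: neighbor-structure index -> (algorithm family, metric)
T_METHODS: dict[int, tuple[str, str]] = {
    1: ("MG", "euclidean"),
    2: ("MG", "pcc"),
    3: ("Icc", "euclidean"),
    4: ("Icc", "pcc"),
}


def alpha_ladder(start: int = 20, stop: int = 70, step: int = 5) -> list[int]:
    """The alpha cuts in percent, default 20, 25, ..., 70."""
    if step <= 0 or stop < start:
        raise ValueError("need step > 0 and stop >= start")
    return list(range(start, stop + 1, step))


def stage_index(alpha: float) -> int:
    """Stage s with alpha_s = 20 + 5(s-1); extended ladders give s <= 0."""
    s = (alpha - 20.0) / 5.0 + 1.0
    if s != int(s):
        raise ValueError(f"alpha={alpha} is not on the 5-percent ladder")
    return int(s)


def e_group_labels(
    efficacy: np.ndarray,
    is_train: np.ndarray,
    alpha: float,
    *,
    unknown_efficacy: np.ndarray | None = None,
    potency_threshold: float = 70.0,
) -> np.ndarray:
    """Vector of E labels: 0 = not training, 1 = E1, 2 = E2, 3 = E3.

    ``unknown_efficacy`` marks training members whose efficacy the method
    must not see (recycled test records): they are forced into E3.
    """
    efficacy = np.asarray(efficacy, dtype=np.float64)
    is_train = np.asarray(is_train, dtype=bool)
    labels = np.zeros(len(efficacy), dtype=np.int64)
    potent = is_train & (efficacy >= potency_threshold)
    ineff = is_train & ~potent
    labels[potent] = 1
    labels[ineff & (efficacy >= alpha)] = 2
    labels[ineff & (efficacy < alpha)] = 3
    if unknown_efficacy is not None:
        labels[is_train & np.asarray(unknown_efficacy, dtype=bool)] = 3
    return labels


def assign_e_groups(
    efficacies: Mapping[str, float], alpha: float, potency_threshold: float = 70.0
) -> dict[str, str]:
    """Per-id E-group names for a training set (convenience wrapper)."""
    ids = list(efficacies)
    eff = np.array([efficacies[i] for i in ids], dtype=np.float64)
    lab = e_group_labels(
        eff, np.ones(len(ids), dtype=bool), alpha, potency_threshold=potency_threshold
    )
    return {i: f"E{l}" for i, l in zip(ids, lab)}


def d_features(group_labels: np.ndarray, e_labels: np.ndarray) -> np.ndarray:
    """(n, 3) matrix of purity triples for one partition.

    ``d(l)`` is the fraction of E_l members among the E-labeled members of the
    sample's group; a group without any E-labeled member yields (0, 0, 0).
    """
    group_labels = np.asarray(group_labels, dtype=np.int64)
    e_labels = np.asarray(e_labels, dtype=np.int64)
    n_groups = int(group_labels.max()) + 1
    counts = np.zeros((n_groups, 3), dtype=np.float64)
    for l in (1, 2, 3):
        counts[:, l - 1] = np.bincount(
            group_labels[e_labels == l], minlength=n_groups
        )
    totals = counts.sum(axis=1)
    per_sample = counts[group_labels]
    denom = totals[group_labels]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(denom[:, None] > 0, per_sample / denom[:, None], 0.0)
    return d


def compute_d(i: int, partition: Partition, e_labels: np.ndarray) -> np.ndarray:
    """Purity triple of sample i under one partition."""
    return d_features(partition.labels, e_labels)[i]


def binarize(d: np.ndarray) -> np.ndarray:
    """(n, 2) binary pairs: c1 = [d1 > d3], c2 = [d1 < d3]; ties -> (0, 0)."""
    d = np.atleast_2d(np.asarray(d, dtype=np.float64))
    c1 = (d[:, 0] > d[:, 2]).astype(np.int64)
    c2 = (d[:, 0] < d[:, 2]).astype(np.int64)
    return np.column_stack([c1, c2])


def binarize_d(d: Sequence[float]) -> tuple[int, int]:
    """Binarized pair of a single purity triple."""
    pair = binarize(np.asarray(d, dtype=np.float64)[None, :])[0]
    return int(pair[0]), int(pair[1])


def aggregate_c(binaries: Sequence[tuple[int, int]]) -> tuple[int, int]:
    """Elementwise sum of the 31 binary pairs of one (record, alpha, t)."""
    if len(binaries) != N_CK:
        raise ValueError(f"expected {N_CK} binary pairs, got {len(binaries)}")
    arr = np.asarray(binaries, dtype=np.int64)
    c1, c2 = arr.sum(axis=0)
    return int(c1), int(c2)


def c_alpha_concat(pairs_by_t: Mapping[int, Sequence[int]]) -> np.ndarray:
    """Concatenate the four aggregate pairs (t = 1..4) into the 8-vector."""
    if sorted(pairs_by_t) != [1, 2, 3, 4]:
        raise ValueError("need aggregate pairs for exactly t = 1, 2, 3, 4")
    return np.concatenate([np.asarray(pairs_by_t[t], dtype=np.int64) for t in (1, 2, 3, 4)])
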