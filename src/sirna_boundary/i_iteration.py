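"""The iterative removal of ineffective siRNAs from the test set.

The boundary between potent and ineffective siRNAs is not built as a global
decision surface.  Instead, at each alpha stage the method computes, for every
potent training record X(i), the aggregate pair ``C^{alpha_s,t}`` and derives
removal thresholds (beta parameters):

* ``beta1`` for t in {1, 2}: the minimum first aggregate over potent training
  records;
* ``beta1`` for t in {3, 4}: the maximum second aggregate over potent training
  records whose first aggregate is zero (+inf if no such record);
* ``beta2`` (any t): the maximum second aggregate over potent training
  records.

A test record is removed when ANY of the following holds:

* t in {1, 2}:  ``c(1) <= beta1``;
* any t:        ``c(2) >= beta2``;
* t in {3, 4}:  ``c(1) = 0`` and ``c(2) >= min(beta1, 16 + s)``.

so that a removed record's overall similarity to low-efficacy training
records exceeds that of every potent training record.  Removed records are
copied into the training data with their efficacy treated as unknown (E3) and
into the I-cluster; passes repeat at fixed alpha until nothing is removed,
then alpha advances.  By default removal stops after alpha = 65% (the 70% cut
only terminates the loop), preventing records near the potency threshold from
being falsely removed.  Test records that survive form the P-cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .base_features import N_CK, feature_matrix
from .data_io import Dataset
from .derived_features import (
    T_METHODS,
    alpha_ladder,
    binarize,
    d_features,
    e_group_labels,
    stage_index,
)
from .neighbor_structures import (
    Partition,
    icc_cluster_from_distances,
    mg_partition_from_distances,
    pairwise_distances,
)

__all__ = ["BetaParams", "RemovalEvent", "IterationState", "IterationEngine",
           "compute_beta", "removal_predicate", "run_iteration"]


@dataclass(frozen=True)
class BetaParams:
    """Removal thresholds of one (stage, t): beta1 may be the +inf sentinel."""

    beta1: float
    beta2: int
    t: int


@dataclass(frozen=True)
class RemovalEvent:
    id: str
    alpha: int
    stage: int
    pass_no: int
    t: int
    condition: str


@dataclass
class IterationState:
    """Outcome of a full run: final memberships, clusters and logs."""

    ids: list[str]
    orig_train: np.ndarray  # bool, original training membership
    removed: np.ndarray  # bool, test records recycled into training
    removal_log: list[RemovalEvent] = field(default_factory=list)
    beta_trace: list[dict] = field(default_factory=list)
    max_aggregate: int = 0
    n_passes: int = 0

    @property
    def p_cluster(self) -> list[str]:
        mask = ~self.orig_train & ~self.removed
        return [i for i, m in zip(self.ids, mask) if m]

    @property
    def i_cluster(self) -> list[str]:
        mask = ~self.orig_train & self.removed
        return [i for i, m in zip(self.ids, mask) if m]

    def cumulative_removals_by_stage(self) -> dict[int, int]:
        """Cumulative removal counts keyed by alpha (non-decreasing)."""
        out: dict[int, int] = {}
        total = 0
        seen: dict[int, int] = {}
        for ev in self.removal_log:
            seen[ev.alpha] = seen.get(ev.alpha, 0) + 1
        for alpha in sorted(seen):
            total += seen[alpha]
            out[alpha] = total
        return out


def compute_beta(aggregates: np.ndarray, potent_mask: np.ndarray, t: int) -> BetaParams:
    """Thresholds from the aggregate pairs of the potent training records."""
    potent_mask = np.asarray(potent_mask, dtype=bool)
    if not potent_mask.any():
        raise ValueError("no potent training records: beta parameters undefined")
    c1 = aggregates[potent_mask, 0]
    c2 = aggregates[potent_mask, 1]
    if t in (1, 2):
        beta1: float = float(c1.min())
    elif t in (3, 4):
        sel = c2[c1 == 0]
        beta1 = float(sel.max()) if sel.size else math.inf
    else:
        raise ValueError(f"t must be 1..4, got {t}")
    return BetaParams(beta1=beta1, beta2=int(c2.max()), t=t)


def removal_predicate(
    pairs_by_t: dict[int, tuple[int, int]],
    betas: dict[int, BetaParams],
    s: int,
) -> tuple[bool, str | None]:
    """Whether one test record is removed at stage s, and the first trigger."""
    for t in (1, 2, 3, 4):
        c1, c2 = pairs_by_t[t]
        b = betas[t]
        if t in (1, 2) and c1 <= b.beta1:
            return True, f"t{t}:c1<=beta1"
        if c2 >= b.beta2:
            return True, f"t{t}:c2>=beta2"
        if t in (3, 4) and c1 == 0 and c2 >= min(b.beta1, 16 + s):
            return True, f"t{t}:c1=0,c2>=min(beta1,16+s)"
    return False, None


class IterationEngine:
    """Precomputes features/partitions for a dataset and drives the removals.

    MG partitions depend only on the sequences and are computed once.  The
    Icc cluster count equals the training-set size; by default the *initial*
    training size is used throughout (``icc_cluster_count="initial"``), which
    keeps the mini-cluster structure stable while records migrate and makes
    the outcome insensitive to where the alpha ladder starts.  With
    ``"current"`` the count tracks the updated training data and the Icc
    partitions are recomputed per alpha stage (``recompute_icc="stage"``) or
    per inner pass (``"pass"``).
    """

    def __init__(
        self,
        dataset: Dataset,
        *,
        recompute_icc: str = "stage",
        icc_cluster_count: str = "initial",
    ) -> None:
        if recompute_icc not in ("stage", "pass"):
            raise ValueError("recompute_icc must be 'stage' or 'pass'")
        if icc_cluster_count not in ("initial", "current"):
            raise ValueError("icc_cluster_count must be 'initial' or 'current'")
        self.icc_cluster_count = icc_cluster_count
        roles = {r.role for r in dataset.records}
        if None in roles:
            raise ValueError("all records need a train/test role before iterating")
        self.dataset = dataset
        self.recompute_icc = recompute_icc
        self.ids = [r.id for r in dataset.records]
        self.sequences = [r.sequence for r in dataset.records]
        self.efficacy = np.array([r.inhibition for r in dataset.records])
        self.orig_train = np.array([r.role == "train" for r in dataset.records])
        self.potency_threshold = dataset.potency_threshold
        self.potent = self.efficacy >= self.potency_threshold
        self.n = len(self.ids)
        if not (self.orig_train & self.potent).any():
            raise ValueError("training data contains no potent record")
        self.max_aggregate = 0
        self._distances: dict[tuple[int, str], np.ndarray] = {}
        self._mg: dict[str, list[np.ndarray]] = {}
        self._icc_cache: dict[tuple[int, str], list[np.ndarray]] = {}

    # ---- partition plumbing -------------------------------------------------

    def _distance(self, k: int, metric: str) -> np.ndarray:
        key = (k, metric)
        if key not in self._distances:
            X = feature_matrix(self.sequences, k)
            self._distances[key] = pairwise_distances(X, metric)
        return self._distances[key]

    def mg_labels(self, metric: str) -> list[np.ndarray]:
        """MG partition labels for all 31 encodings (computed once)."""
        if metric not in self._mg:
            name = "MG1" if metric == "euclidean" else "MG2"
            self._mg[metric] = [
                mg_partition_from_distances(self._distance(k, metric), name).labels
                for k in range(1, N_CK + 1)
            ]
        return self._mg[metric]

    def icc_labels(self, n_clusters: int, metric: str) -> list[np.ndarray]:
        """Icc partition labels for all 31 encodings at one cluster count."""
        key = (n_clusters, metric)
        if key not in self._icc_cache:
            name = "Icc1" if metric == "euclidean" else "Icc2"
            self._icc_cache[key] = [
                icc_cluster_from_distances(
                    self._distance(k, metric), n_clusters, name
                ).labels
                for k in range(1, N_CK + 1)
            ]
        return self._icc_cache[key]

    def partitions_for(self, n_train: int) -> dict[int, list[np.ndarray]]:
        """Labels for t = 1..4 (31 partitions each) at one training size."""
        if self.icc_cluster_count == "initial":
            n_train = int(self.orig_train.sum())
        return {
            1: self.mg_labels("euclidean"),
            2: self.mg_labels("pcc"),
            3: self.icc_labels(n_train, "euclidean"),
            4: self.icc_labels(n_train, "pcc"),
        }

    # ---- derived features ---------------------------------------------------

    def e_labels(self, alpha: float, removed: np.ndarray) -> np.ndarray:
        train = self.orig_train | removed
        return e_group_labels(
            self.efficacy,
            train,
            alpha,
            unknown_efficacy=removed,
            potency_threshold=self.potency_threshold,
        )

    def aggregates(
        self, e_labels: np.ndarray, partitions: dict[int, list[np.ndarray]]
    ) -> dict[int, np.ndarray]:
        """Aggregate pairs C^{alpha,t} for every record, t = 1..4."""
        out: dict[int, np.ndarray] = {}
        for t, labels_by_k in partitions.items():
            agg = np.zeros((self.n, 2), dtype=np.int64)
            for labels in labels_by_k:
                agg += binarize(d_features(labels, e_labels))
            out[t] = agg
        if out:
            self.max_aggregate = max(
                self.max_aggregate, max(int(a.max()) for a in out.values())
            )
        return out

    def c_alpha_matrix(self, alpha: float, removed: np.ndarray) -> np.ndarray:
        """(n, 8) matrix of C^{alpha} vectors for the given training state."""
        n_train = int((self.orig_train | removed).sum())
        aggs = self.aggregates(
            self.e_labels(alpha, removed), self.partitions_for(n_train)
        )
        return np.concatenate([aggs[t] for t in (1, 2, 3, 4)], axis=1)

    # ---- the iteration ------------------------------------------------------

    def run(
        self,
        *,
        alpha_start: int = 20,
        alpha_stop: int = 65,
        alpha_step: int = 5,
    ) -> IterationState:
        """Steps 1-3: per-stage repeated removal passes until a fixed point."""
        state = IterationState(
            ids=self.ids, orig_train=self.orig_train.copy(),
            removed=np.zeros(self.n, dtype=bool),
        )
        is_test = ~self.orig_train
        for alpha in alpha_ladder(alpha_start, alpha_stop, alpha_step):
            s = stage_index(alpha)
            pass_no = 0
            partitions = self.partitions_for(int((self.orig_train | state.removed).sum()))
            while True:
                pass_no += 1
                state.n_passes += 1
                if self.recompute_icc == "pass" and pass_no > 1:
                    partitions = self.partitions_for(
                        int((self.orig_train | state.removed).sum())
                    )
                e = self.e_labels(alpha, state.removed)
                aggs = self.aggregates(e, partitions)
                potent_train = self.orig_train & self.potent
                betas = {t: compute_beta(aggs[t], potent_train, t) for t in (1, 2, 3, 4)}
                for t in (1, 2, 3, 4):
                    state.beta_trace.append(
                        {"alpha": alpha, "stage": s, "pass": pass_no, "t": t,
                         "beta1": betas[t].beta1, "beta2": betas[t].beta2}
                    )
                current_test = np.flatnonzero(is_test & ~state.removed)
                hits = []
                for i in current_test:
                    pairs = {t: (int(aggs[t][i, 0]), int(aggs[t][i, 1])) for t in (1, 2, 3, 4)}
                    flag, cond = removal_predicate(pairs, betas, s)
                    if flag:
                        t_hit = int(cond.split(":")[0][1:])
                        hits.append((int(i), t_hit, cond))
                if not hits:
                    break
                for i, t_hit, cond in hits:  # batch removal: order-independent
                    state.removed[i] = True
                    state.removal_log.append(
                        RemovalEvent(self.ids[i], alpha, s, pass_no, t_hit, cond)
                    )
        state.max_aggregate = self.max_aggregate
        return state


def run_iteration(
    dataset: Dataset,
    *,
    alpha_start: int = 20,
    alpha_stop: int = 65,
    recompute_icc: str = "stage",
    icc_cluster_count: str = "initial",
) -> tuple[IterationEngine, IterationState]:
    """Convenience wrapper: build the engine and run the full iteration."""
    engine = IterationEngine(
        dataset, recompute_icc=recompute_icc, icc_cluster_count=icc_cluster_count
    )
    return engine, engine.run(alpha_start=alpha_start, alpha_stop=alpha_stop)
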