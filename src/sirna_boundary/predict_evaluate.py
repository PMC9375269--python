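"""Efficacy prediction by mini-group averaging, and Se/Sp/PCC evaluation.

After the removal iteration terminates, every test record sits in the
P-cluster (predicted potent) or the I-cluster (predicted ineffective).  Its
efficacy is predicted from the 8-dimensional ``C^{alpha_10}`` aggregate
vectors (alpha_10 = 65%), computed from the updated training data: the
P-cluster together with the potent training records (and, separately, the
I-cluster with the ineffective training records) is partitioned into MG1
mini-groups, and each test record receives the mean experimental efficacy of
the same-class training donors in its mini-group.  A record whose mini-group
holds no donor falls back to the class-wide training mean and is flagged.

Classification is scored against the experimental 70% threshold (sensitivity
``Se = TP/(TP+FN)``, specificity ``Sp = TN/(TN+FP)``), and the predicted
efficacies against the observed ones by the sample Pearson correlation
coefficient (the (b-1)-normalized product of standardized deviations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .i_iteration import IterationEngine, IterationState
from .neighbor_structures import mg_partition

__all__ = [
    "PredictionResult",
    "EvaluationReport",
    "predict_efficacy",
    "confusion",
    "se_sp",
    "pcc",
    "evaluate",
]

ALPHA_PREDICT = 65  # alpha_10 on the default ladder


@dataclass
class EvaluationReport:
    tp: int
    tn: int
    fp: int
    fn: int
    se: float | None
    sp: float | None
    pcc: float | None
    n_test: int

    def to_dict(self) -> dict:
        rounded = lambda v: None if v is None else round(v, 1)
        return {
            "TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
            "Se": self.se, "Sp": self.sp, "PCC": self.pcc, "n_test": self.n_test,
            "Se_display": rounded(self.se), "Sp_display": rounded(self.sp),
            "PCC_display": None if self.pcc is None else round(self.pcc, 2),
        }


def _class_predictions(
    engine: IterationEngine,
    C: np.ndarray,
    member_mask: np.ndarray,
    donor_mask: np.ndarray,
    cluster_name: str,
    rows: dict[str, dict],
) -> None:
    members = np.flatnonzero(member_mask)
    test_members = np.flatnonzero(member_mask & ~engine.orig_train)
    if test_members.size == 0:
        return
    if not donor_mask.any():
        raise ValueError(f"no training donors available for the {cluster_name}-cluster")
    donor_mean = float(engine.efficacy[donor_mask].mean())
    if members.size < 2:
        # a lone test record cannot form a mini-group; fall back to class mean
        for i in test_members:
            rows[engine.ids[i]] = {
                "cluster": cluster_name, "predicted": donor_mean,
                "group": 1, "n_donors": 0, "fallback": True,
            }
        return
    part = mg_partition(C[members], metric="euclidean")
    donor_local = donor_mask[members]
    eff_local = engine.efficacy[members]
    for local, i in enumerate(members):
        if engine.orig_train[i]:
            continue
        in_group = part.labels == part.labels[local]
        donors = in_group & donor_local
        n_donors = int(donors.sum())
        if n_donors:
            pred = float(eff_local[donors].mean())
            fallback = False
        else:
            pred = donor_mean
            fallback = True
        rows[engine.ids[i]] = {
            "cluster": cluster_name, "predicted": pred,
            "group": int(part.labels[local]), "n_donors": n_donors,
            "fallback": fallback,
        }


def predict_efficacy(
    engine: IterationEngine, state: IterationState, alpha: int = ALPHA_PREDICT
) -> pd.DataFrame:
    """Per-test-record predictions (id, observed, predicted, cluster, ...)."""
    C = engine.c_alpha_matrix(alpha, state.removed).astype(np.float64)
    is_test = ~engine.orig_train
    p_mask = is_test & ~state.removed
    i_mask = is_test & state.removed
    potent_train = engine.orig_train & engine.potent
    ineff_train = engine.orig_train & ~engine.potent
    rows: dict[str, dict] = {}
    _class_predictions(engine, C, p_mask | potent_train, potent_train, "P", rows)
    _class_predictions(engine, C, i_mask | ineff_train, ineff_train, "I", rows)
    out = []
    for i in np.flatnonzero(is_test):
        rid = engine.ids[i]
        row = rows[rid]
        out.append(
            {
                "id": rid,
                "sequence": engine.sequences[i],
                "observed": float(engine.efficacy[i]),
                "predicted": row["predicted"],
                "cluster": row["cluster"],
                "group": row["group"],
                "n_donors": row["n_donors"],
                "fallback": row["fallback"],
            }
        )
    return pd.DataFrame(out)


def confusion(
    state: IterationState, truth_potent: dict[str, bool]
) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN): P-cluster counts as predicted potent."""
    tp = sum(truth_potent[i] for i in state.p_cluster)
    fp = sum(not truth_potent[i] for i in state.p_cluster)
    fn = sum(truth_potent[i] for i in state.i_cluster)
    tn = sum(not truth_potent[i] for i in state.i_cluster)
    return tp, tn, fp, fn


def se_sp(tp: int, tn: int, fp: int, fn: int) -> tuple[float | None, float | None]:
    """Sensitivity and specificity in percent; None when undefined."""
    se = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else None
    sp = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else None
    return se, sp


def pcc(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Sample Pearson correlation, (b-1)-normalized sum of standardized products."""
    x = np.asarray(predicted, dtype=np.float64)
    y = np.asarray(observed, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("predicted and observed must be 1-D vectors of equal length")
    b = len(x)
    if b < 2:
        raise ValueError("PCC needs at least 2 samples")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0.0 or sy == 0.0:
        raise ValueError("PCC undefined for a zero-variance vector")
    return float(np.sum((x - x.mean()) / sx * ((y - y.mean()) / sy)) / (b - 1))


def evaluate(
    state: IterationState, predictions: pd.DataFrame, truth_potent: dict[str, bool]
) -> EvaluationReport:
    tp, tn, fp, fn = confusion(state, truth_potent)
    se, sp = se_sp(tp, tn, fp, fn)
    try:
        rho = pcc(predictions["predicted"].to_numpy(), predictions["observed"].to_numpy())
    except ValueError:
        rho = None
    return EvaluationReport(
        tp=tp, tn=tn, fp=fp, fn=fn, se=se, sp=sp, pcc=rho, n_test=tp + tn + fp + fn
    )
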