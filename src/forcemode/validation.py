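"""Leave-one-trajectory-out cross-validation and model-quality metrics.

Each replica (trajectory) is held out in turn; the PLS model fitted on
the remaining replicas predicts the held-out difference vector. On
replicas that underwent the conformational transition the prediction is
scored by ROC AUC (per-frame binary state against the predicted value)
and by Pearson correlation; on control replicas that stayed in the down
state the per-frame false-positive fraction is reported instead. The
per-fold coefficient vectors are sign-aligned and averaged into the
ensemble PLS vector, and chain-symmetry diagnostics compare coefficients
between the two chains of the dimer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .constants import STATE_THRESHOLD
from .pls import (RankDeficiencyWarning, component_contribution,
                  ensemble_average_vectors, fit_pls, predict,
                  select_n_components)

TRANSITION = "transition"
CONTROL = "control"


@dataclass
class Replica:
    """One trajectory's feature matrix, observable and state labels."""

    features: np.ndarray
    observable: np.ndarray
    labels: np.ndarray
    replica_id: str = ""
    kind: str = ""

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.observable = np.asarray(self.observable, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if not self.kind:
            self.kind = TRANSITION if np.any(self.labels == 1) else CONTROL


@dataclass
class ReplicaResult:
    replica_id: str
    kind: str
    auc: float | None
    pearson_r: float | None
    false_positive_fraction: float | None


@dataclass
class ValidationReport:
    """Cross-validation outcome across all replicas."""

    per_replica: list[ReplicaResult]
    ensemble_vector: np.ndarray
    vector_similarity: np.ndarray
    first_component_contribution: list[float]
    n_components: int
    threshold: float = STATE_THRESHOLD
    fold_vectors: list[np.ndarray] = field(default_factory=list, repr=False)
    predictions: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.per_replica])

    def min_transition_auc(self) -> float:
        return min(r.auc for r in self.per_replica if r.auc is not None)

    def min_transition_pearson(self) -> float:
        return min(r.pearson_r for r in self.per_replica
                   if r.kind == TRANSITION and r.pearson_r is not None)


def roc_auc(scores, labels) -> float:
    """ROC area under curve, Mann-Whitney formulation.

    The fraction of (positive, negative) frame pairs in which the
    positive frame scores higher, ties counted one half; computed from
    average ranks.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must share shape")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)
    u = float(np.sum(ranks[labels == 1])) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def cross_validate(replicas, n_components: int | str = "auto",
                   threshold: float = STATE_THRESHOLD,
                   max_components: int = 20) -> ValidationReport:
    """Leave-one-replica-out cross-validation of the PLS force model.

    ``replicas`` may be :class:`Replica` objects or (features,
    observable, labels) tuples. With ``n_components="auto"`` the
    component count is chosen by the held-out-correlation policy of
    :func:`forcemode.pls.select_n_components`.
    """
    reps = [r if isinstance(r, Replica) else Replica(*r, replica_id=str(i))
            for i, r in enumerate(replicas)]
    for i, r in enumerate(reps):
        if not r.replica_id:
            r.replica_id = str(i)
    if len(reps) < 2:
        raise ValueError("cross-validation requires at least two replicas")

    if n_components == "auto":
        k = select_n_components(reps, max_components=max_components)
    else:
        k = int(n_components)

    results, fold_vectors, contributions, predictions = [], [], [], {}
    for i, held in enumerate(reps):
        X_train = np.vstack([r.features for j, r in enumerate(reps) if j != i])
        y_train = np.concatenate([r.observable for j, r in enumerate(reps)
                                  if j != i])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RankDeficiencyWarning)
            model = fit_pls(X_train, y_train, k)
        pred = predict(model, held.features)
        predictions[held.replica_id] = pred
        fold_vectors.append(model.coefficient_vector)
        contributions.append(float(
            component_contribution(model, X_train, y_train)[0]))

        pearson = (float(np.corrcoef(pred, held.observable)[0, 1])
                   if np.std(held.observable) > 0 and np.std(pred) > 0 else None)
        if len(np.unique(held.labels)) == 2:
            auc = roc_auc(pred, held.labels)
            fpr = None
        else:
            # single-class replica: report per-frame false positives instead
            auc = None
            fpr = float(np.mean((pred > threshold) != (held.labels == 1)))
        results.append(ReplicaResult(held.replica_id, held.kind, auc,
                                     pearson, fpr))

    ensemble_vector, similarity = ensemble_average_vectors(fold_vectors)
    return ValidationReport(results, ensemble_vector, similarity,
                            contributions, k, threshold, fold_vectors,
                            predictions)


@dataclass
class ChainSymmetryResult:
    """Paired chain A/B coefficients and their agreement statistics."""

    pairs: pd.DataFrame
    pearson_r: float
    top_positive_ranks: pd.DataFrame
    top_negative_ranks: pd.DataFrame
    unpaired: list[str]


def chain_symmetry(coefficient_vector, residue_ids, chain_pairing,
                   top_k: int = 5) -> ChainSymmetryResult:
    """Compare PLS coefficients between the two chains of the dimer.

    ``chain_pairing`` maps each chain-A residue id to its chain-B
    equivalent. Besides the paired coefficient table and their Pearson
    correlation, the partner's rank is reported for the ``top_k`` most
    positive and most negative chain-A residues (rank 1 = most
    positive/negative within chain B).
    """
    coef = np.asarray(coefficient_vector, dtype=float)
    index = {rid: i for i, rid in enumerate(residue_ids)}
    if isinstance(chain_pairing, pd.DataFrame):
        chain_pairing = dict(zip(chain_pairing.iloc[:, 0],
                                 chain_pairing.iloc[:, 1]))
    rows, unpaired = [], []
    for a_id, b_id in chain_pairing.items():
        if a_id in index and b_id in index:
            rows.append((a_id, b_id, coef[index[a_id]], coef[index[b_id]]))
        else:
            unpaired.append(a_id if a_id not in index else b_id)
    if len(rows) < 2:
        raise ValueError("need at least two paired residues")
    pairs = pd.DataFrame(rows, columns=["residue_a", "residue_b",
                                        "coef_a", "coef_b"])
    r = float(np.corrcoef(pairs["coef_a"], pairs["coef_b"])[0, 1])

    def _ranks(ascending: bool) -> pd.DataFrame:
        ordered_a = pairs.sort_values("coef_a", ascending=ascending,
                                      kind="mergesort")
        rank_b = pairs["coef_b"].rank(ascending=ascending, method="min")
        out = ordered_a.head(top_k).copy()
        out["partner_rank_in_b"] = rank_b.loc[out.index].astype(int).values
        return out.reset_index(drop=True)

    return ChainSymmetryResult(pairs, r, _ranks(False), _ranks(True), unpaired)


def top_residues(coefficient_vector, residue_ids, k: int = 5):
    """The k most positive and k most negative coefficients.

    Returns two DataFrames (residue_id, coefficient) ordered by
    decreasing |coefficient|; ties broken by ascending residue position
    for deterministic output.
    """
    coef = np.asarray(coefficient_vector, dtype=float)
    if not 1 <= k <= len(coef) // 2:
        raise ValueError("k must be at most half the number of residues")
    order = np.lexsort((np.arange(len(coef)), -coef))
    pos = order[:k]
    order_neg = np.lexsort((np.arange(len(coef)), coef))
    neg = order_neg[:k]
    make = lambda idx: pd.DataFrame({
        "residue_id": [residue_ids[i] for i in idx],
        "coefficient": coef[idx]})
    return make(pos), make(neg)
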