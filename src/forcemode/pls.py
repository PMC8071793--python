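"""Partial-least-squares functional mode analysis (PLS1, NIPALS).

Given per-frame feature vectors (here: per-residue punctual-stress
vectors) and a scalar observable (here: the conformational difference
vector), PLS iteratively builds orthogonal score directions that
maximise covariance with the observable, then composes them into a
single regression coefficient vector in feature (residue) space — the
"PLS vector" whose entries rank residues by how strongly their lipid
force signal tracks the conformational change.

Features are mean-centred but deliberately *not* variance-scaled, so
coefficients stay comparable across residues in physical force units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


class DegenerateTargetError(ValueError):
    """The observable has zero variance; nothing to regress on."""


class UndefinedContributionError(ValueError):
    """Full-model R^2 is not positive; component fractions are undefined."""


class RankDeficiencyWarning(UserWarning):
    """Requested more components than the data support."""


@dataclass
class PLSModel:
    """Fitted PLS1 model.

    ``weight_vectors`` (p x K) are the unit NIPALS weights, ``loadings``
    (p x K) the X-loadings, ``y_loadings`` (K,) the per-component
    regression weights on the scores. ``coefficient_vector`` composes all
    K components into a single length-p vector so that predictions are

        y_hat = y_mean + (X - x_mean) @ coefficient_vector.
    """

    x_mean: np.ndarray
    y_mean: float
    weight_vectors: np.ndarray
    loadings: np.ndarray
    y_loadings: np.ndarray
    n_components: int
    scores: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_features(self) -> int:
        return len(self.x_mean)

    def coefficients(self, n_components: int | None = None) -> np.ndarray:
        """Coefficient vector of the model truncated to the first
        ``n_components`` components (all K by default)."""
        k = self.n_components if n_components is None else int(n_components)
        if not 1 <= k <= self.n_components:
            raise ValueError(f"n_components must be in [1, {self.n_components}]")
        W = self.weight_vectors[:, :k]
        P = self.loadings[:, :k]
        q = self.y_loadings[:k]
        return W @ np.linalg.solve(P.T @ W, q)

    @property
    def coefficient_vector(self) -> np.ndarray:
        return self.coefficients()


def fit_pls(X, y, n_components: int) -> PLSModel:
    """Fit single-response PLS by NIPALS.

    Per component: the weight vector is the (unit-normalised) covariance
    direction X_res^T y_res, scores t = X_res w, then X and y are
    deflated by the rank-one score contribution. If the data cannot
    support the requested number of components the model is truncated
    with a :class:`RankDeficiencyWarning`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y must have the same number of frames")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("X and y must be finite")
    if not 1 <= n_components < n:
        raise ValueError("require frames > n_components >= 1")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    if np.max(np.abs(yc)) == 0.0:
        raise DegenerateTargetError("observable has zero variance")

    scale = float(np.linalg.norm(Xc.T @ yc))
    W, P, Q, T = [], [], [], []
    for _ in range(n_components):
        w = Xc.T @ yc
        nw = float(np.linalg.norm(w))
        if nw <= 1e-12 * max(scale, 1.0):
            warnings.warn(f"data rank supports only {len(W)} of "
                          f"{n_components} requested components",
                          RankDeficiencyWarning, stacklevel=2)
            break
        w /= nw
        t = Xc @ w
        tt = float(t @ t)
        if tt <= 1e-24:
            warnings.warn(f"data rank supports only {len(W)} of "
                          f"{n_components} requested components",
                          RankDeficiencyWarning, stacklevel=2)
            break
        pvec = Xc.T @ t / tt
        qk = float(yc @ t) / tt
        Xc = Xc - np.outer(t, pvec)
        yc = yc - qk * t
        W.append(w); P.append(pvec); Q.append(qk); T.append(t)

    if not W:
        raise DegenerateTargetError("observable is uncorrelated with every "
                                    "feature; no component can be extracted")
    return PLSModel(x_mean=x_mean, y_mean=y_mean,
                    weight_vectors=np.column_stack(W),
                    loadings=np.column_stack(P),
                    y_loadings=np.asarray(Q),
                    n_components=len(W),
                    scores=np.column_stack(T))


def predict(model: PLSModel, X, n_components: int | None = None) -> np.ndarray:
    """Predicted observable for new feature rows."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValueError(f"X has {X.shape[1]} columns, model expects "
                         f"{model.n_features}")
    return model.y_mean + (X - model.x_mean) @ model.coefficients(n_components)


def _r_squared(y, y_hat) -> float:
    y = np.asarray(y, dtype=float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateTargetError("observable has zero variance")
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / ss_tot


def component_contribution(model: PLSModel, X, y) -> np.ndarray:
    """Cumulative component contributions as fractions of the full model.

    Entry k-1 is R^2 of the model truncated to the first k components
    divided by R^2 of the full model on the same data; entry 0 is the
    contribution of the first PLS eigenvector (the ensemble-weighted
    collective force mode).
    """
    y = np.asarray(y, dtype=float)
    r2_full = _r_squared(y, predict(model, X))
    if r2_full <= 0.0:
        raise UndefinedContributionError("full-model R^2 is not positive")
    return np.array([_r_squared(y, predict(model, X, k)) / r2_full
                     for k in range(1, model.n_components + 1)])


def ensemble_average_vectors(vectors):
    """Sign-aligned arithmetic mean of coefficient vectors.

    Any vector with negative dot product against the first is flipped
    before averaging (PLS vectors are sign-ambiguous across training
    sets only up to orientation of the fit). Returns the mean vector and
    the pairwise cosine-similarity matrix of the sign-aligned vectors.
    """
    vectors = [np.asarray(v, dtype=float) for v in vectors]
    if not vectors:
        raise ValueError("need at least one vector")
    p = len(vectors[0])
    if any(len(v) != p for v in vectors):
        raise ValueError("all vectors must have equal length")
    ref = vectors[0]
    aligned = np.stack([v if float(v @ ref) >= 0.0 else -v for v in vectors])
    norms = np.linalg.norm(aligned, axis=1)
    norms = np.where(norms == 0.0, 1.0, norms)
    unit = aligned / norms[:, None]
    return aligned.mean(axis=0), unit @ unit.T


def select_n_components(replicas, max_components: int = 20,
                        tol: float = 0.01) -> int:
    """Pick the number of PLS components by held-out-replica correlation.

    Each replica is held out in turn; the model is fitted on the rest at
    ``max_components`` and evaluated, truncated at every k, on the
    held-out frames. The selected K is the smallest whose mean Pearson
    correlation (over held-out replicas with a transition) improves by
    less than ``tol`` over K-1, capped at ``max_components``.

    ``replicas`` is a sequence of objects exposing ``features``,
    ``observable`` and ``labels`` (see :mod:`forcemode.validation`).
    """
    if len(replicas) < 2:
        raise ValueError("need at least two replicas")
    eval_idx = [i for i, r in enumerate(replicas) if np.any(np.asarray(r.labels) == 1)]
    if not eval_idx:
        eval_idx = list(range(len(replicas)))
    per_fold_r = []
    for i in eval_idx:
        X_train = np.vstack([r.features for j, r in enumerate(replicas) if j != i])
        y_train = np.concatenate([r.observable for j, r in enumerate(replicas)
                                  if j != i])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RankDeficiencyWarning)
            model = fit_pls(X_train, y_train, max_components)
        held = replicas[i]
        rs = []
        for k in range(1, model.n_components + 1):
            pred = predict(model, held.features, k)
            rs.append(float(np.corrcoef(pred, held.observable)[0, 1]))
        per_fold_r.append(rs)
    kmax = min(len(rs) for rs in per_fold_r)
    mean_r = np.array([np.mean([rs[k] for rs in per_fold_r])
                       for k in range(kmax)])
    for k in range(1, kmax):
        if mean_r[k] - mean_r[k - 1] < tol:
            return k + 1
    return kmax
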