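"""Stepwise linear discriminant analysis (SWLDA).

The de-facto P300 epoch classifier: forward-backward stepwise regression of
the {0, 1} target label on the flattened amplitude features by ordinary
least squares (entry at p < 0.05, removal at p > 0.10 by default), followed
by an OLS linear decision rule that emits hard 0/1 labels at a fixed score
threshold.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .types import EpochSet, FeatureMatrix
from .preprocess import to_features as _to_features

logger = logging.getLogger(__name__)

_RANK_TOL = 1e-10


@dataclass
class SwldaModel:
    """Selected feature indices, linear weights and the hard-label rule."""

    selected: np.ndarray               # ordered feature indices
    weights: np.ndarray                # one weight per selected feature
    intercept: float
    threshold: float = 0.5
    p_enter: float = 0.05
    p_remove: float = 0.10
    train_meta: dict = field(default_factory=dict)
    feature_map: list[tuple[str, float]] | None = None

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.selected.size != self.weights.size:
            raise ValueError("weights length must equal selection length")

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Linear score per row; 0.5 sits between the class codes 0 and 1."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.selected.size == 0:
            return np.full(X.shape[0], -np.inf)
        if X.shape[1] <= self.selected.max():
            raise ValueError(
                f"feature vector of length {X.shape[1]} does not cover "
                f"selected index {int(self.selected.max())}"
            )
        return X[:, self.selected] @ self.weights + self.intercept

    def to_json(self) -> str:
        doc = {
            "selected": self.selected.tolist(),
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "threshold": self.threshold,
            "p_enter": self.p_enter,
            "p_remove": self.p_remove,
            "train_meta": self.train_meta,
            "feature_map": self.feature_map,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SwldaModel":
        doc = json.loads(text)
        fmap = doc.get("feature_map")
        if fmap is not None:
            fmap = [(str(c), float(t)) for c, t in fmap]
        return cls(
            selected=np.asarray(doc["selected"], dtype=int),
            weights=np.asarray(doc["weights"], dtype=float),
            intercept=float(doc["intercept"]),
            threshold=float(doc["threshold"]),
            p_enter=float(doc["p_enter"]),
            p_remove=float(doc["p_remove"]),
            train_meta=doc.get("train_meta", {}),
            feature_map=fmap,
        )


def _ols_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Coefficient p-values (excluding intercept) of OLS y ~ 1 + X."""
    import statsmodels.api as sm

    res = sm.OLS(y, sm.add_constant(X)).fit()
    return np.asarray(res.pvalues)[1:]


def stepwise_select(
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_features: int = 60,
) -> np.ndarray:
    """Forward-backward stepwise regression of y on the columns of X.

    At each forward step the candidate with the smallest partial p-value is
    added if p < ``p_enter`` (ties broken toward the lowest column index);
    after each addition, included features whose full-model p exceeds
    ``p_remove`` are dropped, worst first. Rank-deficient candidates are
    skipped with a log note. Deterministic given its inputs.
    """
    if isinstance(X, FeatureMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y disagree on the number of epochs")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("y contains a single class; both classes are required")

    selected: list[int] = []
    if max_features <= 0:
        return np.asarray(selected, dtype=int)

    sqrt_n = np.sqrt(n)
    ref = np.sqrt(np.mean(X**2, axis=0)) + 1.0  # per-column degeneracy scale

    while len(selected) < max_features:
        k = len(selected)
        # Orthonormal basis of [1, X[:, selected]] built once per step.
        Q = np.empty((n, k + 1))
        Q[:, 0] = 1.0 / sqrt_n
        for j, col in enumerate(selected):
            v = X[:, col] - Q[:, : j + 1] @ (Q[:, : j + 1].T @ X[:, col])
            Q[:, j + 1] = v / np.linalg.norm(v)

        cand = np.setdiff1d(np.arange(p), selected, assume_unique=False)
        if cand.size == 0:
            break
        y_r = y - Q @ (Q.T @ y)
        ss_y = float(y_r @ y_r)
        df = n - (k + 1) - 1
        if df <= 0 or ss_y <= 0:
            break
        Xc = X[:, cand]
        R = Xc - Q @ (Q.T @ Xc)
        ss_x = np.einsum("ij,ij->j", R, R)
        xy = R.T @ y_r
        degenerate = ss_x <= (_RANK_TOL * n) * ref[cand] ** 2
        if degenerate.any():
            logger.info(
                "stepwise_select: skipping %d rank-deficient candidate(s)",
                int(degenerate.sum()),
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            expl = xy**2 / ss_x
            resid = np.maximum(ss_y - expl, 0.0)
            t2 = expl / (resid / df)
        t2[degenerate | ~np.isfinite(t2)] = 0.0
        pvals = 2.0 * stats.t.sf(np.sqrt(t2), df)
        pvals[degenerate] = np.inf
        best = int(np.argmin(pvals))  # first minimum = lowest index on ties
        if not pvals[best] < p_enter:
            break
        selected.append(int(cand[best]))

        # Backward pass: drop worst included feature while p > p_remove.
        while len(selected) > 1:
            pv = _ols_pvalues(X[:, selected], y)
            worst = int(np.argmax(pv))
            if pv[worst] > p_remove:
                dropped = selected.pop(worst)
                logger.info("stepwise_select: removed feature %d", dropped)
            else:
                break

    return np.asarray(selected, dtype=int)


def fit_linear(
    X_selected: np.ndarray,
    y: np.ndarray,
    selected: np.ndarray | None = None,
    threshold: float = 0.5,
) -> SwldaModel:
    """OLS weights on the selected columns with y coded {0, 1}.

    The decision rule labels an epoch 1 when the linear score is >= the
    threshold (default 0.5, the midpoint of the class codes).
    """
    X_selected = np.atleast_2d(np.asarray(X_selected, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X_selected.shape[1] == 0:
        raise ValueError("selection is empty; nothing to fit")
    design = np.column_stack([np.ones(X_selected.shape[0]), X_selected])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    if selected is None:
        selected = np.arange(X_selected.shape[1])
    return SwldaModel(
        selected=np.asarray(selected, dtype=int),
        weights=coef[1:],
        intercept=float(coef[0]),
        threshold=threshold,
    )


def predict_labels(model: SwldaModel, X: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Hard 0/1 labels; a score exactly at the threshold labels 1."""
    if isinstance(X, FeatureMatrix):
        X = X.values
    if model.selected.size == 0:
        warnings.warn(
            "SwldaModel has an empty selection; predicting all nontarget",
            stacklevel=2,
        )
        return np.zeros(np.atleast_2d(X).shape[0], dtype=int)
    return (model.decision_scores(X) >= model.threshold).astype(int)


def predict_label(model: SwldaModel, features: np.ndarray) -> int:
    """Hard label for a single epoch's feature vector."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 1:
        raise ValueError("predict_label expects a single feature vector")
    return int(predict_labels(model, features[None, :])[0])


def train_swlda(
    epochs: EpochSet | FeatureMatrix,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_features: int = 60,
    threshold: float = 0.5,
    feature_sfreq: float = 128.0,
) -> SwldaModel:
    """Features -> stepwise selection -> OLS refit on the selected set."""
    if isinstance(epochs, EpochSet):
        features = _to_features(epochs, feature_sfreq)
    else:
        features = epochs
    y = features.labels
    if y is None:
        raise ValueError("training features carry no labels")
    selected = stepwise_select(features, y, p_enter, p_remove, max_features)
    if selected.size == 0:
        model = SwldaModel(
            selected=selected, weights=np.empty(0), intercept=0.0,
            threshold=threshold,
        )
    else:
        model = fit_linear(features.values[:, selected], y, selected, threshold)
    model.p_enter = p_enter
    model.p_remove = p_remove
    model.feature_map = features.feature_map
    model.train_meta = {
        "n_target": int(np.sum(y == 1)),
        "n_nontarget": int(np.sum(y == 0)),
        "n_selected": int(selected.size),
    }
    return model
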