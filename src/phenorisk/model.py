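"""Race-stratified linear max-margin risk model.

The classifier is a linear support-vector machine (hinge loss, L2 penalty
— LinearSVC) trained per race stratum on balanced case/control data.  Its
single hyperparameter, the cost ``C``, is chosen by stratified k-fold
cross-validation maximizing AUC of the decision scores; ties break toward
the smaller (more regularized) ``C``.  The emitted risk score is the signed
distance to the separating hyperplane, ``w . x + b`` — unbounded, higher
means more dementia-like — and is thresholded downstream at empirical
percentiles of the full validation population.

The module follows the Model/Results idiom: build a
:class:`DementiaRiskModel` from a feature matrix and labels, call
``fit()``, and work with the returned :class:`DementiaRiskResults`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .features import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = ["SvmSpec", "DementiaRiskModel", "DementiaRiskResults",
           "select_C", "score_percentiles"]


@dataclass(frozen=True)
class SvmSpec:
    """Hyperparameter search space and solver settings."""

    C_grid: tuple[float, ...] = (1e-4, 1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2)
    n_folds: int = 5
    seed: int = 0
    loss: str = "hinge"
    tol: float = 1e-4
    max_iter: int = 50000

    def __post_init__(self):
        if not self.C_grid or any(c <= 0 for c in self.C_grid):
            raise ValueError("C_grid must be non-empty and strictly positive")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


def _make_svc(C: float, spec: SvmSpec) -> LinearSVC:
    return LinearSVC(C=C, loss=spec.loss, penalty="l2", dual=True,
                     tol=spec.tol, max_iter=spec.max_iter,
                     random_state=spec.seed)


def _validate_xy(X: np.ndarray, y: np.ndarray) -> None:
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in feature matrix")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")


def select_C(X: np.ndarray, y: np.ndarray, spec: SvmSpec) -> tuple[float, pd.DataFrame]:
    """Choose C by stratified k-fold CV on decision-score AUC.

    Returns the chosen C and the CV table (C, mean fold AUC).  Deterministic
    given the spec seed; AUC ties break toward the smaller C.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    _validate_xy(X, y)
    folds = StratifiedKFold(n_splits=spec.n_folds, shuffle=True,
                            random_state=spec.seed)
    rows = []
    for C in sorted(spec.C_grid):
        aucs = []
        for tr, te in folds.split(X, y):
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
                raise ValueError("a CV fold lost one class; need more data per class")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf = _make_svc(C, spec).fit(X[tr], y[tr])
            aucs.append(roc_auc_score(y[te], clf.decision_function(X[te])))
        rows.append({"C": C, "cv_auc": float(np.mean(aucs))})
    table = pd.DataFrame(rows)
    best = table.loc[table["cv_auc"].idxmax()]  # idxmax -> first max -> smallest C
    logger.info("select_C: chose C=%g (CV AUC %.4f)", best["C"], best["cv_auc"])
    return float(best["C"]), table


def score_percentiles(scores: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Percentile of each score within a reference population (mean rank).

    With ``reference`` equal to ``scores`` this is the empirical percentile
    rank within the population itself, in (0, 100].
    """
    ref = np.sort(np.asarray(reference, dtype=np.float64))
    s = np.asarray(scores, dtype=np.float64)
    left = np.searchsorted(ref, s, side="left")
    right = np.searchsorted(ref, s, side="right")
    return 100.0 * (left + right) / (2.0 * len(ref))


class DementiaRiskModel:
    """Linear SVM risk model over an assembled feature matrix.

    Parameters
    ----------
    endog : array-like of {0, 1}
        Case/control labels (1 = case).
    exog : FeatureMatrix or DataFrame or ndarray
        Patient-by-feature design matrix.
    spec : SvmSpec
        Solver and cross-validation settings.
    """

    def __init__(self, endog, exog, spec: SvmSpec = SvmSpec(),
                 feature_names: Sequence[str] | None = None):
        if isinstance(exog, FeatureMatrix):
            self.feature_names = exog.feature_names
            self.exog = exog.values
        elif isinstance(exog, pd.DataFrame):
            self.feature_names = list(exog.columns)
            self.exog = exog.to_numpy(dtype=np.float64)
        else:
            self.exog = np.asarray(exog, dtype=np.float64)
            self.feature_names = (list(feature_names) if feature_names is not None
                                  else [f"x{i}" for i in range(self.exog.shape[1])])
        if len(self.feature_names) != self.exog.shape[1]:
            raise ValueError("feature_names length does not match matrix width")
        self.endog = np.asarray(endog).astype(int)
        if len(self.endog) != self.exog.shape[0]:
            raise ValueError("endog length does not match matrix height")
        self.spec = spec
        _validate_xy(self.exog, self.endog)

    @classmethod
    def from_feature_matrix(cls, fm: FeatureMatrix, labels: pd.Series,
                            spec: SvmSpec = SvmSpec()) -> "DementiaRiskModel":
        """Build from a FeatureMatrix and a patient_id-indexed label series."""
        y = labels.reindex(fm.data.index)
        if y.isna().any():
            raise ValueError("labels missing for some patients in the feature matrix")
        return cls(y.to_numpy(), fm, spec)

    def fit(self, C: float | None = None) -> "DementiaRiskResults":
        """Select C by CV (unless given), then fit on the full training data."""
        if C is None:
            chosen_C, cv_table = select_C(self.exog, self.endog, self.spec)
        else:
            chosen_C, cv_table = float(C), pd.DataFrame(columns=["C", "cv_auc"])
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            clf = _make_svc(chosen_C, self.spec).fit(self.exog, self.endog)
            if any(issubclass(w.category, ConvergenceWarning) for w in caught):
                logger.warning("fit: solver did not reach tol=%g within %d iterations",
                               self.spec.tol, self.spec.max_iter)
        w = clf.coef_.ravel().astype(np.float64)
        b = float(clf.intercept_[0])
        if not (np.isfinite(w).all() and np.isfinite(b)):
            raise RuntimeError("non-finite weights after fitting")
        return DementiaRiskResults(self, w, b, chosen_C, cv_table)


class DementiaRiskResults:
    """Fitted risk model: weights, intercept, chosen C and CV diagnostics."""

    def __init__(self, model: DementiaRiskModel, weights: np.ndarray,
                 intercept: float, chosen_C: float, cv_table: pd.DataFrame):
        if len(weights) != len(model.feature_names):
            raise ValueError("weight length must equal feature count")
        self.model = model
        self.weights = weights
        self.intercept = intercept
        self.chosen_C = chosen_C
        self.cv_table = cv_table

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.weights, index=self.model.feature_names, name="weight")

    def score(self, exog) -> np.ndarray:
        """Risk scores: signed distance to the hyperplane, w . x + b."""
        if isinstance(exog, FeatureMatrix):
            if exog.feature_names != self.model.feature_names:
                raise ValueError("feature names do not match the fitted model")
            X = exog.values
        elif isinstance(exog, pd.DataFrame):
            if list(exog.columns) != self.model.feature_names:
                raise ValueError("feature names do not match the fitted model")
            X = exog.to_numpy(dtype=np.float64)
        else:
            X = np.asarray(exog, dtype=np.float64)
            if X.shape[1] != len(self.weights):
                raise ValueError("feature count does not match the fitted model")
        return X @ self.weights + self.intercept

    def score_frame(self, exog, reference_scores: np.ndarray | None = None) -> pd.DataFrame:
        """Scores plus percentiles against a reference population.

        The reference defaults to the scored population itself; pass the full
        validation stratum's scores when scoring a subset.
        """
        scores = self.score(exog)
        if isinstance(exog, FeatureMatrix):
            pids = exog.patient_ids
        elif isinstance(exog, pd.DataFrame):
            pids = exog.index.to_numpy()
        else:
            pids = np.arange(len(scores))
        ref = scores if reference_scores is None else reference_scores
        return pd.DataFrame({
            "patient_id": pids,
            "score": scores,
            "percentile": score_percentiles(scores, ref),
        })

    def training_auc(self) -> float:
        return float(roc_auc_score(self.model.endog, self.score(self.model.exog)))

    def summary(self, top: int = 10) -> str:
        """Readable fit report: chosen C, CV table, largest-|w| features."""
        lines = ["Linear SVM dementia risk model",
                 "=" * 34,
                 f"n obs:        {len(self.model.endog)}",
                 f"n features:   {len(self.weights)}",
                 f"chosen C:     {self.chosen_C:g}",
                 f"training AUC: {self.training_auc():.4f}",
                 f"intercept:    {self.intercept:+.4f}",
                 ""]
        if len(self.cv_table):
            lines.append("CV AUC by C:")
            for r in self.cv_table.itertuples():
                flag = "  <- chosen" if r.C == self.chosen_C else ""
                lines.append(f"  C={r.C:<8g} auc={r.cv_auc:.4f}{flag}")
            lines.append("")
        lines.append(f"top {top} features by |weight|:")
        p = self.params
        for name, w in p.reindex(p.abs().sort_values(ascending=False).index)[:top].items():
            lines.append(f"  {w:+.4f}  {name}")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        payload = {
            "feature_names": self.model.feature_names,
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "chosen_C": self.chosen_C,
            "seed": self.model.spec.seed,
            "cv_table": self.cv_table.to_dict(orient="records"),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "DementiaRiskResults":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        n = len(payload["feature_names"])
        stub = DementiaRiskModel.__new__(DementiaRiskModel)
        stub.feature_names = payload["feature_names"]
        stub.exog = np.zeros((0, n))
        stub.endog = np.zeros(0, dtype=int)
        stub.spec = SvmSpec(seed=payload.get("seed", 0))
        return cls(stub, np.asarray(payload["weights"], dtype=np.float64),
                   float(payload["intercept"]), float(payload["chosen_C"]),
                   pd.DataFrame(payload.get("cv_table", [])))
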