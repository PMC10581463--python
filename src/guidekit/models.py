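"""Random-forest models for guide efficiency and SNV-outcome prediction.

The modelling surface follows the Model/Results convention: a model object is
built from a feature matrix and labels, ``fit()`` trains the forest and
returns a Results object carrying the fitted estimator, out-of-bag error,
feature importances and (optionally) cross-validation metrics, with a
``summary()`` table.

Hyperparameters stay at scikit-learn defaults except the number of trees
(450). Regression OOB error is the OOB mean squared error; classification OOB
error is the OOB misclassification rate. Regression predictions are clipped to
[0, 100] efficiency units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import (
    confusion_matrix,
    mean_squared_error,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

from .features import SCHEMA_VERSION, tokenize_many

DEFAULT_N_TREES = 450
DEFAULT_FOLDS = 5

BASES = "ACGT"


# ---------------------------------------------------------------------------
# validation metrics
# ---------------------------------------------------------------------------

def percentile_ranks(values) -> np.ndarray:
    """Percentile rank of each value within the list, on a 0-100 scale.

    Uses the mean-of-strict-and-weak convention (all-equal input -> all 50),
    which is order-preserving.
    """
    values = np.asarray(values, dtype=float)
    return np.array(
        [stats.percentileofscore(values, v, kind="mean") for v in values]
    )


@dataclass
class ValidationReport:
    task: str
    n: int
    mse: float | None = None
    pearson_r: float | None = None
    pearson_p: float | None = None
    spearman_rho: float | None = None
    spearman_p: float | None = None
    truth_percentiles: np.ndarray | None = None
    pred_percentiles: np.ndarray | None = None
    confusion: pd.DataFrame | None = None
    per_class_accuracy: dict | None = None
    accuracy: float | None = None
    roc_curves: dict | None = None
    auc: dict | None = None
    mean_auc: float | None = None

    def summary(self) -> str:
        lines = [f"Validation report ({self.task}, n={self.n})"]
        if self.task == "regression":
            lines.append(f"  MSE          : {self.mse:.6g}")
            if self.pearson_r is None:
                lines.append("  Pearson r    : undefined (zero variance)")
            else:
                lines.append(
                    f"  Pearson r    : {self.pearson_r:.4f} (p={self.pearson_p:.3g})"
                )
                lines.append(
                    f"  Spearman rho : {self.spearman_rho:.4f} (p={self.spearman_p:.3g})"
                )
        else:
            lines.append(f"  Accuracy     : {self.accuracy:.4f}")
            if self.mean_auc is not None:
                lines.append(f"  Mean OvA AUC : {self.mean_auc:.4f}")
            lines.append("  Confusion matrix (rows=truth):")
            lines.extend("    " + ln for ln in str(self.confusion).splitlines())
        return "\n".join(lines)


def validate(truths, predictions, task: str = "regression",
             scores: np.ndarray | None = None,
             classes: Sequence[str] | None = None) -> ValidationReport:
    """Compare predictions to truths.

    Regression: MSE, Pearson/Spearman with two-sided p (reported as missing
    when either vector has zero variance) and percentile ranks of both lists.
    Classification: confusion matrix, per-class and overall accuracy, and
    one-vs-all ROC/AUC when per-class probability `scores` are supplied.
    """
    truths = np.asarray(truths)
    predictions = np.asarray(predictions)
    if len(truths) != len(predictions):
        raise ValueError("length mismatch")
    if len(truths) < 3:
        raise ValueError("need at least 3 pairs")
    if task == "regression":
        t = truths.astype(float)
        p = predictions.astype(float)
        report = ValidationReport(task="regression", n=len(t))
        report.mse = float(mean_squared_error(t, p))
        if np.std(t) == 0 or np.std(p) == 0:
            report.pearson_r = None
        else:
            r, rp = stats.pearsonr(t, p)
            rho, sp = stats.spearmanr(t, p)
            report.pearson_r, report.pearson_p = float(r), float(rp)
            report.spearman_rho, report.spearman_p = float(rho), float(sp)
        report.truth_percentiles = percentile_ranks(t)
        report.pred_percentiles = percentile_ranks(p)
        return report
    if task == "classification":
        labels = sorted(set(truths) | set(predictions)) if classes is None else list(classes)
        cm = confusion_matrix(truths, predictions, labels=labels)
        cm_df = pd.DataFrame(cm, index=labels, columns=labels)
        per_class = {
            lab: (cm[i, i] / cm[i].sum() if cm[i].sum() else float("nan"))
            for i, lab in enumerate(labels)
        }
        report = ValidationReport(
            task="classification",
            n=len(truths),
            confusion=cm_df,
            per_class_accuracy=per_class,
            accuracy=float(np.trace(cm) / cm.sum()),
        )
        if scores is not None:
            scores = np.asarray(scores, dtype=float)
            rocs, aucs = {}, {}
            for i, lab in enumerate(labels):
                y = (truths == lab).astype(int)
                if y.sum() in (0, len(y)):
                    continue
                fpr, tpr, _ = roc_curve(y, scores[:, i])
                rocs[lab] = (fpr, tpr)
                aucs[lab] = float(roc_auc_score(y, scores[:, i]))
            report.roc_curves = rocs
            report.auc = aucs
            report.mean_auc = float(np.mean(list(aucs.values()))) if aucs else None
        return report
    raise ValueError(f"unknown task {task!r}")


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    task: str = "regression",
    folds: int = DEFAULT_FOLDS,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
) -> dict:
    """k-fold cross-validation (stratified for classification).

    Returns per-fold metrics, their means, and the out-of-fold predictions
    aligned with the input order. Raises if a class has fewer members than
    folds (naming the class).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if n < folds:
        raise ValueError(f"n={n} < folds={folds}")
    if task == "classification":
        labels, counts = np.unique(y, return_counts=True)
        for lab, c in zip(labels, counts):
            if c < folds:
                raise ValueError(
                    f"class {lab!r} has {c} member(s), fewer than {folds} folds"
                )
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split = splitter.split(X, y)
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        split = splitter.split(X)
    oof = np.empty(n, dtype=object if task == "classification" else float)
    fold_metrics = []
    fold_assign = np.empty(n, dtype=int)
    for k, (train_idx, test_idx) in enumerate(split):
        forest = _make_forest(task, n_trees, seed + k, oob=False)
        forest.fit(X[train_idx], y[train_idx])
        pred = forest.predict(X[test_idx])
        oof[test_idx] = pred
        fold_assign[test_idx] = k
        if task == "regression":
            t = y[test_idx].astype(float)
            m = {"mse": float(mean_squared_error(t, pred))}
            if np.std(t) > 0 and np.std(pred) > 0:
                r, _ = stats.pearsonr(t, pred)
                rho, _ = stats.spearmanr(t, pred)
                m["pearson_r"] = float(r)
                m["spearman_rho"] = float(rho)
            else:
                m["pearson_r"] = float("nan")
                m["spearman_rho"] = float("nan")
        else:
            m = {"accuracy": float(np.mean(pred == y[test_idx]))}
        fold_metrics.append(m)
    means = {
        key: float(np.nanmean([fm[key] for fm in fold_metrics]))
        for key in fold_metrics[0]
    }
    return {
        "folds": fold_metrics,
        "mean": means,
        "oof_predictions": oof if task == "classification" else oof.astype(float),
        "fold_assignment": fold_assign,
    }


def _make_forest(task: str, n_trees: int, seed: int, oob: bool):
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if task == "regression":
        return RandomForestRegressor(
            n_estimators=n_trees, oob_score=oob, random_state=seed, n_jobs=1
        )
    return RandomForestClassifier(
        n_estimators=n_trees, oob_score=oob, random_state=seed, n_jobs=1
    )


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class _ForestModel:
    """Shared machinery for the two forest models."""

    task: str = ""

    def __init__(self, X, y, schema: Sequence[str] | None = None,
                 n_trees: int = DEFAULT_N_TREES):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError("X and y lengths differ")
        if schema is not None and len(schema) != X.shape[1]:
            raise ValueError("schema length does not match feature count")
        self.X = X
        self.y = y
        self.schema = tuple(schema) if schema is not None else tuple(
            f"f{i}" for i in range(X.shape[1])
        )
        self.n_trees = n_trees

    @classmethod
    def from_sequences(cls, sequences: Sequence[str], y, **kwargs):
        """Build the model by tokenising raw sequences (all feature families)."""
        X, schema = tokenize_many(sequences)
        return cls(X, y, schema=schema, **kwargs)

    def cross_validate(self, folds: int = DEFAULT_FOLDS, seed: int = 0) -> dict:
        return cross_validate(
            self.X, self.y, task=self.task, folds=folds,
            n_trees=self.n_trees, seed=seed,
        )

    def _fit_forest(self, seed: int):
        forest = _make_forest(self.task, self.n_trees, seed, oob=True)
        forest.fit(self.X, self.y)
        return forest


class GuideEfficiencyModel(_ForestModel):
    """Random-forest regression of guide cleavage efficiency (0-100 scale)
    on tokenised sequence features."""

    task = "regression"

    def __init__(self, X, y, schema=None, n_trees: int = DEFAULT_N_TREES):
        super().__init__(X, y, schema=schema, n_trees=n_trees)
        y = self.y.astype(float)
        if len(y) < 10:
            raise ValueError("need at least 10 training samples")
        self.y = y

    @classmethod
    def from_training_table(cls, table: pd.DataFrame,
                            efficiency_col: str = "efficiency",
                            context_col: str = "context", **kwargs):
        """Build from a screen training table (see screen.build_training_table)."""
        return cls.from_sequences(
            table[context_col].tolist(), table[efficiency_col].to_numpy(), **kwargs
        )

    def fit(self, seed: int = 0, cv_folds: int | None = None) -> "ForestResults":
        forest = self._fit_forest(seed)
        oob_pred = forest.oob_prediction_
        oob_error = float(mean_squared_error(self.y, oob_pred))
        cv = self.cross_validate(folds=cv_folds, seed=seed) if cv_folds else None
        return ForestResults(self, forest, seed=seed, oob_error=oob_error, cv=cv)


class SnvOutcomeModel(_ForestModel):
    """Random-forest multiclass classifier of the SNV outcome base at an
    editing hotspot, from the tokenised target window (default 39 nt).

    With the reference base excluded there are three possible outcomes per
    target, so chance accuracy is 1/3. Rows whose label equals the reference
    base (if `reference_bases` is given) are rejected.
    """

    task = "classification"

    def __init__(self, X, y, schema=None, n_trees: int = DEFAULT_N_TREES,
                 reference_bases: Sequence[str] | None = None):
        y = np.asarray(y, dtype=object)
        bad = [lab for lab in np.unique(y) if lab not in set(BASES)]
        if bad:
            raise ValueError(f"labels must be in A/C/G/T, got {bad}")
        if reference_bases is not None:
            clash = np.asarray(reference_bases, dtype=object) == y
            if clash.any():
                raise ValueError(
                    f"{int(clash.sum())} row(s) have an outcome equal to the "
                    "reference base; remove them before fitting"
                )
        super().__init__(X, y, schema=schema, n_trees=n_trees)
        self.chance_accuracy = 1.0 / 3.0

    def fit(self, seed: int = 0, cv_folds: int | None = None) -> "ForestResults":
        forest = self._fit_forest(seed)
        oob_error = 1.0 - float(forest.oob_score_)  # misclassification rate
        cv = self.cross_validate(folds=cv_folds, seed=seed) if cv_folds else None
        return ForestResults(self, forest, seed=seed, oob_error=oob_error, cv=cv)


@dataclass
class ForestResults:
    """Fitted forest plus its diagnostics.

    ``oob_error`` is the OOB MSE for regression and the OOB misclassification
    rate for classification.
    """

    model: _ForestModel
    forest: object
    seed: int
    oob_error: float
    cv: dict | None = None
    schema_version: str = field(default=SCHEMA_VERSION)

    @property
    def task(self) -> str:
        return self.model.task

    def predict(self, X=None, sequences: Sequence[str] | None = None) -> np.ndarray:
        if sequences is not None:
            X, schema = tokenize_many(sequences)
            if schema != self.model.schema:
                raise ValueError(
                    "feature schema at predict time differs from training schema"
                )
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.model.schema):
            raise ValueError("feature count mismatch with training schema")
        pred = self.forest.predict(X)
        if self.task == "regression":
            pred = np.clip(pred, 0.0, 100.0)
        return pred

    def predict_proba(self, X=None, sequences: Sequence[str] | None = None):
        if self.task != "classification":
            raise ValueError("probabilities only defined for classification")
        if sequences is not None:
            X, _ = tokenize_many(sequences)
        return self.forest.predict_proba(np.asarray(X, dtype=float))

    def feature_importance(self) -> list[tuple[str, float]]:
        """(feature, weight) pairs, weights >= 0 summing to 1, sorted
        descending; ties broken by schema order."""
        weights = np.asarray(self.forest.feature_importances_, dtype=float)
        order = sorted(
            range(len(weights)), key=lambda i: (-weights[i], i)
        )
        return [(self.model.schema[i], float(weights[i])) for i in order]

    def holdout_report(self, test_size: float = 0.2, seed: int | None = None
                       ) -> ValidationReport:
        """Refit on a seeded shuffled train split and validate on the rest
        (the 80/20 visualisation protocol)."""
        seed = self.seed if seed is None else seed
        idx = np.arange(len(self.model.y))
        stratify = self.model.y if self.task == "classification" else None
        train_idx, test_idx = train_test_split(
            idx, test_size=test_size, random_state=seed, shuffle=True,
            stratify=stratify,
        )
        forest = _make_forest(self.task, self.model.n_trees, seed, oob=False)
        forest.fit(self.model.X[train_idx], self.model.y[train_idx])
        pred = forest.predict(self.model.X[test_idx])
        if self.task == "regression":
            return validate(self.model.y[test_idx], np.clip(pred, 0, 100),
                            task="regression")
        scores = forest.predict_proba(self.model.X[test_idx])
        return validate(self.model.y[test_idx], pred, task="classification",
                        scores=scores, classes=list(forest.classes_))

    def summary(self) -> str:
        lines = [
            f"{type(self.model).__name__} results",
            f"  task        : {self.task}",
            f"  n samples   : {len(self.model.y)}",
            f"  n features  : {len(self.model.schema)}",
            f"  n trees     : {self.model.n_trees}",
            f"  seed        : {self.seed}",
            f"  OOB error   : {self.oob_error:.4f} "
            + ("(MSE)" if self.task == "regression" else "(misclassification rate)"),
        ]
        if self.cv:
            for key, val in self.cv["mean"].items():
                lines.append(f"  CV mean {key:<12}: {val:.4f}")
        top = self.feature_importance()[:5]
        lines.append("  top features: " + ", ".join(f"{n}={w:.3f}" for n, w in top))
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialise forest + schema; writes a JSON metadata sidecar."""
        path = Path(path)
        payload = {
            "forest": self.forest,
            "schema": self.model.schema,
            "schema_version": self.schema_version,
            "task": self.task,
            "n_trees": self.model.n_trees,
            "seed": self.seed,
            "oob_error": self.oob_error,
        }
        joblib.dump(payload, path)
        sidecar = {
            "task": self.task,
            "n_trees": self.model.n_trees,
            "n_features": len(self.model.schema),
            "schema_version": self.schema_version,
            "seed": self.seed,
            "oob_error": self.oob_error,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2)
        )


class LoadedModel:
    """Prediction-only wrapper around a serialised model artifact."""

    def __init__(self, payload: dict):
        self.forest = payload["forest"]
        self.schema = tuple(payload["schema"])
        self.schema_version = payload["schema_version"]
        self.task = payload["task"]

    @classmethod
    def load(cls, path: str | Path) -> "LoadedModel":
        payload = joblib.load(path)
        if payload.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(
                f"model was built with feature schema "
                f"{payload.get('schema_version')!r}, this build uses {SCHEMA_VERSION!r}"
            )
        return cls(payload)

    def predict_sequences(self, sequences: Sequence[str]) -> np.ndarray:
        X, schema = tokenize_many(sequences)
        if schema != self.schema:
            raise ValueError("sequence tokenisation does not match model schema")
        pred = self.forest.predict(X)
        if self.task == "regression":
            pred = np.clip(pred, 0.0, 100.0)
        return pred


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------

def train_regressor(X, y, n_trees: int = DEFAULT_N_TREES, seed: int = 0,
                    schema=None) -> ForestResults:
    return GuideEfficiencyModel(X, y, schema=schema, n_trees=n_trees).fit(seed=seed)


def train_snv_classifier(X, y, n_trees: int = DEFAULT_N_TREES, seed: int = 0,
                         schema=None, reference_bases=None) -> ForestResults:
    return SnvOutcomeModel(
        X, y, schema=schema, n_trees=n_trees, reference_bases=reference_bases
    ).fit(seed=seed)


def feature_importance(results: ForestResults) -> list[tuple[str, float]]:
    return results.feature_importance()
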