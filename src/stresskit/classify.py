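"""Three-level stress classification (stress / relax / neutral).

Epochs are labeled from the protocol: minutes 7-8 of the stress session
(counted from training onset, i.e. inside the task's final third) are
*stress*, minutes 2-3 of the relaxation session are *relax*, and the
central minute of each resting-state block is *neutral* -- 60 two-second
epochs per class, 180 per subject.

The classifier is a linear discriminant: per-class means with a pooled
within-class covariance (plus a small ridge for degenerate folds) and
equal priors, matching the balanced design.  Two cross-validation
schemes are provided: leave-one-epoch-out within a subject, and
leave-one-subject-out across the cohort.  Accuracy comes with a normal-
approximation binomial 95% CI, half-width 1.96 * sqrt(p(1-p)/n).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .session import EventTimeline

__all__ = [
    "CLASS_ORDER",
    "label_epochs",
    "class_windows",
    "StressLda",
    "fit_lda",
    "predict",
    "loocv",
    "loso",
    "accuracy_ci",
    "AccuracyResult",
    "format_percent",
    "accuracy_table",
]

#: fixed class order; also the deterministic tie-break order
CLASS_ORDER = ("stress", "relax", "neutral")

ALL_MARKERS = ("RG", "HR", "TA", "SC")


def class_windows(timeline: EventTimeline) -> dict[str, list[tuple[float, float]]]:
    """Label windows per class (seconds).  The stress window counts
    minutes 7-8 from the start of the stress-session training block."""
    t = timeline
    return {
        "stress": [(t.mist_train_start + 360.0, t.mist_train_start + 480.0)],
        "relax": [(t.relax_start + 60.0, t.relax_start + 180.0)],
        "neutral": [
            (t.rs1_start + 30.0, t.rs1_start + 90.0),
            (t.rs2_start + 30.0, t.rs2_start + 90.0),
        ],
    }


def label_epochs(
    markers: pd.DataFrame,
    timeline: EventTimeline,
    expected_per_class: int | None = 60,
) -> pd.DataFrame:
    """Attach class labels to marker epochs inside the label windows.

    Returns the labeled subset with a ``label`` column.  With the
    default 2-s epochs each class must yield ``expected_per_class``
    rows per subject (pass None to skip the check).
    """
    wins = class_windows(timeline)
    if wins["stress"][0][1] > timeline.mist_end + 1e-9:
        raise ValueError("stress label window extends past the end of the stress session")
    if wins["relax"][0][1] > timeline.relax_end + 1e-9:
        raise ValueError("relax label window needs at least 180 s of relaxation session")

    out = markers.copy()
    out["label"] = None
    for label, windows in wins.items():
        for s, e in windows:
            sel = (out["epoch_start_s"] >= s - 1e-9) & (out["epoch_start_s"] < e - 1e-9)
            out.loc[sel, "label"] = label
    out = out.dropna(subset=["label"]).reset_index(drop=True)

    if expected_per_class is not None:
        counts = (
            out.groupby(["subject_id", "label"], sort=True).size().unstack(fill_value=0)
        )
        bad = counts[(counts != expected_per_class).any(axis=1)]
        if not bad.empty:
            raise ValueError(
                f"expected {expected_per_class} epochs per class per subject, got:\n{bad}"
            )
    return out


class StressLda(ClassifierMixin, BaseEstimator):
    """Linear discriminant analysis with pooled covariance and equal priors.

    Fitted attributes: ``classes_``, ``means_`` (per class), and
    ``covariance_`` (pooled within-class, with ridge
    ``ridge * trace/dim`` added to the diagonal).  Ties in the
    discriminant scores break deterministically by the fixed class
    order stress < relax < neutral (then alphabetically for other
    label sets).
    """

    def __init__(self, ridge: float = 1e-6):
        self.ridge = ridge

    @staticmethod
    def _class_sort_key(label):
        try:
            return (0, CLASS_ORDER.index(label))
        except ValueError:
            return (1, label)

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        classes = sorted(set(y), key=self._class_sort_key)
        if len(classes) < 2:
            raise ValueError("need at least 2 classes in training data")
        self.classes_ = np.asarray(classes, dtype=object)
        d = X.shape[1]
        means = np.empty((len(classes), d))
        pooled = np.zeros((d, d))
        n = 0
        for k, c in enumerate(classes):
            xk = X[np.asarray(y, dtype=object) == c]
            if xk.shape[0] < 1:
                raise ValueError(f"class {c!r} absent from training data")
            means[k] = xk.mean(axis=0)
            r = xk - means[k]
            pooled += r.T @ r
            n += xk.shape[0]
        pooled /= max(n - len(classes), 1)
        pooled += np.eye(d) * self.ridge * (np.trace(pooled) / d + 1e-300)
        self.means_ = means
        self.covariance_ = pooled
        self.priors_ = np.full(len(classes), 1.0 / len(classes))
        self._coef = np.linalg.solve(pooled, means.T).T          # (k, d)
        self._intercept = -0.5 * np.einsum("kd,kd->k", self._coef, means)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "means_")
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.means_.shape[1]:
            raise ValueError(
                f"X has {X.shape[1]} features; model was fitted with {self.means_.shape[1]}"
            )
        return X @ self._coef.T + self._intercept

    def predict(self, X):
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]


@dataclass
class LdaModel:
    """Thin functional view of a fitted :class:`StressLda`."""

    estimator: StressLda

    @property
    def class_means(self):
        return dict(zip(self.estimator.classes_, self.estimator.means_))


def fit_lda(train: pd.DataFrame, features: tuple[str, ...] = ALL_MARKERS) -> LdaModel:
    """Fit the discriminant on a labeled marker table."""
    est = StressLda().fit(train[list(features)].to_numpy(), train["label"].to_numpy())
    model = LdaModel(est)
    model.features = tuple(features)
    return model


def predict(model: LdaModel, x) -> np.ndarray | str:
    """Predict label(s) for one feature vector or a batch."""
    arr = np.asarray(x, float)
    single = arr.ndim == 1
    out = model.estimator.predict(np.atleast_2d(arr))
    return out[0] if single else out


@dataclass
class AccuracyResult:
    """Classification success probability with its binomial 95% CI."""

    p_a: float
    n: int
    ci_half_width: float
    confusion: pd.DataFrame  # rows true, columns predicted
    subject_id: str | None = None

    @property
    def percent(self) -> str:
        return format_percent(self.p_a, self.ci_half_width)


def accuracy_ci(p_a: float, n: int) -> float:
    """Half-width of the binomial normal-approximation 95% CI."""
    if not 0.0 <= p_a <= 1.0:
        raise ValueError(f"p_a must be in [0, 1], got {p_a}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return 1.96 * math.sqrt(p_a * (1.0 - p_a) / n)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def format_percent(p_a: float, half_width: float) -> str:
    """Render an accuracy as the tables do: integer percent, half-up."""
    return f"{_round_half_up(100 * p_a)} ± {_round_half_up(100 * half_width)}"


def _evaluate(y_true, y_pred, classes, subject_id=None) -> AccuracyResult:
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    n = y_true.size
    conf = pd.DataFrame(0, index=list(classes), columns=list(classes), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf.loc[t, p] += 1
    p_a = float((y_true == y_pred).mean())
    return AccuracyResult(p_a, n, accuracy_ci(p_a, n), conf, subject_id)


def loocv(dataset: pd.DataFrame, features: tuple[str, ...] = ALL_MARKERS) -> AccuracyResult:
    """Leave-one-epoch-out cross-validation within one labeled dataset.

    Folds whose training split loses a class entirely are skipped with a
    warning and n adjusted.
    """
    X = dataset[list(features)].to_numpy(float)
    y = dataset["label"].to_numpy(object)
    n = X.shape[0]
    if n < 2:
        raise ValueError("leave-one-out needs at least 2 observations")
    preds, trues = [], []
    skipped = 0
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        if len(set(y[mask])) < 2:
            skipped += 1
            continue
        est = StressLda().fit(X[mask], y[mask])
        preds.append(est.predict(X[i : i + 1])[0])
        trues.append(y[i])
    if skipped:
        warnings.warn(f"{skipped} fold(s) skipped: a class vanished from training")
    classes = sorted(set(y), key=StressLda._class_sort_key)
    sid = dataset["subject_id"].iloc[0] if "subject_id" in dataset else None
    return _evaluate(trues, preds, classes, subject_id=sid)


def loso(
    per_subject: list[pd.DataFrame], features: tuple[str, ...] = ALL_MARKERS
) -> list[AccuracyResult]:
    """Leave-one-subject-out: classify each subject's epochs with a
    model trained on all other subjects."""
    if len(per_subject) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    results = []
    for i, held in enumerate(per_subject):
        train = pd.concat([d for j, d in enumerate(per_subject) if j != i], ignore_index=True)
        model = fit_lda(train, features)
        y_pred = model.estimator.predict(held[list(features)].to_numpy(float))
        classes = sorted(set(train["label"]), key=StressLda._class_sort_key)
        sid = held["subject_id"].iloc[0] if "subject_id" in held else str(i)
        results.append(_evaluate(held["label"].to_numpy(object), y_pred, classes, sid))
    return results


def accuracy_table(
    per_subject: list[pd.DataFrame],
    feature_sets: list[tuple[str, ...]],
    cv: str = "loocv",
) -> pd.DataFrame:
    """Per-subject accuracy table over feature subsets, with a mean row;
    shaped like the study's summary tables ("NN ± M" plus raw floats)."""
    if cv not in ("loocv", "loso"):
        raise ValueError(f"cv must be 'loocv' or 'loso', got {cv!r}")
    cols = {}
    for features in feature_sets:
        name = ", ".join(features)
        if cv == "loocv":
            res = [loocv(d, features) for d in per_subject]
        else:
            res = loso(per_subject, features)
        cols[name] = res
    rows = []
    for i, d in enumerate(per_subject):
        sid = d["subject_id"].iloc[0] if "subject_id" in d else str(i + 1)
        row = {"subject_id": sid}
        for name, res in cols.items():
            row[name] = res[i].percent
            row[name + " (p_a)"] = res[i].p_a
        rows.append(row)
    mean_row = {"subject_id": "Mean ± Std"}
    for name, res in cols.items():
        p = np.array([r.p_a for r in res])
        mean_row[name] = (
            f"{_round_half_up(100 * p.mean())} ± {_round_half_up(100 * p.std(ddof=1))}"
        )
        mean_row[name + " (p_a)"] = p.mean()
    rows.append(mean_row)
    return pd.DataFrame(rows)
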