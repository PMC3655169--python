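"""RBF-SVM training, cross-validation, and patient-level ROC evaluation.

The classifier is a soft-margin support vector machine with a Gaussian
(RBF) kernel.  Features are z-scored with statistics learned on the
training rows; the fitted model is stored explicitly (support vectors
x_i, signed weights a_i*y_i, bias b, kernel width gamma) so that the
decision function

    f(x) = sum_i a_i * y_i * exp(-gamma * ||x_i - x||^2) + b

can be evaluated by this module directly, independent of the solver used
to fit it.  The quadratic-programming dual is solved by scikit-learn's
SVC; everything downstream of the fitted coefficients is computed here.

Patient-level evaluation uses the *malignance rate*: the fraction of a
patient's ROIs predicted malignant.  This per-patient score drives the
ROC sweep; the AUC equals the Mann-Whitney statistic U/(n+ * n-) (ties
get half credit) and its p-value against AUC = 0.5 comes from the
tie-corrected normal approximation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, StratifiedGroupKFold, StratifiedKFold
from sklearn.svm import SVC

from .balance import LabeledTable

__all__ = [
    "SvmModel",
    "EvalResult",
    "train_svm",
    "decision_value",
    "decision_values",
    "predict",
    "kfold_cv",
    "malignance_rate",
    "roc_auc",
    "chi_square_2x2",
    "feature_change",
]

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "malignant"


@dataclass
class SvmModel:
    """An RBF-SVM in explicit decision-function form."""

    support_vectors: np.ndarray  # s x d, in z-scored feature space
    alphas: np.ndarray  # s signed weights a_i * y_i
    bias: float
    gamma: float
    C: float
    scale_mean: np.ndarray
    scale_sd: np.ndarray
    classes: List[str]  # [negative, positive]; f > 0 predicts classes[1]

    @property
    def n_features(self) -> int:
        return self.support_vectors.shape[1]

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "support_vectors": self.support_vectors.tolist(),
            "alphas": self.alphas.tolist(),
            "bias": self.bias,
            "gamma": self.gamma,
            "C": self.C,
            "scale_mean": self.scale_mean.tolist(),
            "scale_sd": self.scale_sd.tolist(),
            "classes": self.classes,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "SvmModel":
        d = json.loads(Path(path).read_text())
        return cls(
            np.asarray(d["support_vectors"], float),
            np.asarray(d["alphas"], float),
            float(d["bias"]),
            float(d["gamma"]),
            float(d["C"]),
            np.asarray(d["scale_mean"], float),
            np.asarray(d["scale_sd"], float),
            list(d["classes"]),
        )


@dataclass
class EvalResult:
    fold_accuracies: List[float]
    mean_accuracy: float
    per_patient: pd.DataFrame  # patient_id, label, malignance_rate
    roc: List[Tuple[float, float, float]]  # (fpr, tpr, threshold)
    auc: float
    auc_p: float
    extras: Dict[str, object] = field(default_factory=dict)


def _as_xy(t: Union[LabeledTable, Tuple[np.ndarray, Sequence]]) -> Tuple[np.ndarray, np.ndarray]:
    if isinstance(t, LabeledTable):
        return t.X, t.y
    X, y = t
    return np.asarray(X, float), np.asarray(y)


def train_svm(
    t: Union[LabeledTable, Tuple[np.ndarray, Sequence]],
    C: float = 1.0,
    gamma: Union[str, float] = "scale",
    seed: int = 0,
    tol: float = 1e-7,
) -> SvmModel:
    """Fit the RBF-SVM on z-scored features.

    ``gamma`` follows the usual convention: "scale" resolves to
    1 / (d * var(z-scored X)), or pass a positive float.
    """
    X, y = _as_xy(t)
    classes = sorted(np.unique(y).tolist())
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    if C <= 0:
        raise ValueError("C must be > 0")

    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mean) / sd
    if gamma == "scale":
        var = Z.var()
        gamma_val = 1.0 / (Z.shape[1] * var) if var > 0 else 1.0
    else:
        gamma_val = float(gamma)
        if gamma_val <= 0:
            raise ValueError("gamma must be > 0")

    clf = SVC(C=C, kernel="rbf", gamma=gamma_val, tol=tol, random_state=seed)
    clf.fit(Z, y)
    # sklearn orders dual_coef_ by classes_; its sign convention already
    # encodes a_i * y_i with classes_[1] as the positive class.
    return SvmModel(
        support_vectors=clf.support_vectors_.copy(),
        alphas=clf.dual_coef_.ravel().copy(),
        bias=float(clf.intercept_[0]),
        gamma=gamma_val,
        C=C,
        scale_mean=mean,
        scale_sd=sd,
        classes=[str(c) for c in clf.classes_],
    )


def decision_values(m: SvmModel, X: np.ndarray) -> np.ndarray:
    """Evaluate f(x) = sum_i a_i y_i K(x_i, x) + b for each row of X."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != m.n_features:
        raise ValueError(
            f"expected {m.n_features} features, got {X.shape[1]}"
        )
    Z = (X - m.scale_mean) / m.scale_sd
    d2 = (
        (Z**2).sum(axis=1)[:, None]
        + (m.support_vectors**2).sum(axis=1)[None, :]
        - 2.0 * Z @ m.support_vectors.T
    )
    K = np.exp(-m.gamma * np.clip(d2, 0.0, None))
    return K @ m.alphas + m.bias


def decision_value(m: SvmModel, x: np.ndarray) -> float:
    return float(decision_values(m, np.atleast_2d(x))[0])


def predict(m: SvmModel, X: np.ndarray) -> np.ndarray:
    f = decision_values(m, X)
    return np.where(f > 0, m.classes[1], m.classes[0])


def kfold_cv(
    t: Union[LabeledTable, Tuple[np.ndarray, Sequence]],
    k: int = 10,
    grouping: str = "patient",
    groups: Optional[Sequence] = None,
    C: float = 1.0,
    gamma: Union[str, float] = "scale",
    seed: int = 0,
) -> Dict[str, object]:
    """Stratified k-fold cross-validation.

    grouping="patient" (with ``groups`` = per-row patient ids) keeps all
    ROIs of a patient in one fold, avoiding leakage of a patient's other
    scans into training; grouping="roi" stratifies rows independently.
    Returns fold accuracies, their mean, and out-of-fold predictions.
    """
    X, y = _as_xy(t)
    n = len(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if grouping == "patient":
        if groups is None:
            raise ValueError("grouping='patient' requires per-row groups")
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(X, y, groups=np.asarray(groups))
    elif grouping == "roi":
        _, class_counts = np.unique(y, return_counts=True)
        if k > class_counts.min():
            # stratification is infeasible (e.g. leave-one-out); plain
            # shuffled folds still satisfy the proportions-within-1 contract
            splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
            split = splitter.split(X)
        else:
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
            split = splitter.split(X, y)
    else:
        raise ValueError("grouping must be 'patient' or 'roi'")

    oof = np.empty(n, dtype=object)
    accs: List[float] = []
    assignment = np.full(n, -1, dtype=int)
    for fold, (tr, te) in enumerate(split):
        model = train_svm((X[tr], y[tr]), C=C, gamma=gamma, seed=seed)
        pred = predict(model, X[te])
        oof[te] = pred
        assignment[te] = fold
        accs.append(float((pred == y[te]).mean()))
    return {
        "fold_accuracies": accs,
        "mean_accuracy": float(np.mean(accs)),
        "oof_predictions": oof,
        "fold_assignment": assignment,
    }


def malignance_rate(predictions: Sequence[str], positive: str = POSITIVE_LABEL) -> float:
    """Fraction of a patient's ROIs predicted malignant."""
    predictions = list(predictions)
    if len(predictions) == 0:
        raise ValueError("a patient needs at least one ROI prediction")
    return sum(p == positive for p in predictions) / len(predictions)


def roc_auc(
    scores: Sequence[float], labels: Sequence[str], positive: str = POSITIVE_LABEL
) -> Dict[str, object]:
    """ROC by threshold sweep, trapezoid AUC, Mann-Whitney p-value.

    The sweep predicts positive when score >= threshold, over the unique
    scores in descending order (plus a sentinel above the maximum), so
    tied positive/negative scores contribute half credit to the AUC —
    exactly the Mann-Whitney convention.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = labels == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    roc: List[Tuple[float, float, float]] = []
    for thr in thresholds:
        called = scores >= thr
        tpr = float((called & pos).sum() / n_pos)
        fpr = float((called & ~pos).sum() / n_neg)
        roc.append((fpr, tpr, float(thr)))
    fprs = np.array([p[0] for p in roc])
    tprs = np.array([p[1] for p in roc])
    auc = float(np.trapezoid(tprs, fprs))

    # Normal approximation for U = auc * n_pos * n_neg, with tie correction.
    n = n_pos + n_neg
    _, tie_counts = np.unique(scores, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    sigma2 = n_pos * n_neg / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        p_value = 1.0
    else:
        z = (auc * n_pos * n_neg - n_pos * n_neg / 2.0) / np.sqrt(sigma2)
        p_value = float(2.0 * stats.norm.sf(abs(z)))
    return {"roc": roc, "auc": auc, "auc_p": p_value}


def chi_square_2x2(table: Sequence[Sequence[float]]) -> Tuple[float, int, float]:
    """Pearson chi-square on a 2x2 contingency table, no continuity correction."""
    table = np.asarray(table, float)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("every margin must be positive")
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)


def feature_change(
    features: pd.DataFrame,
    feature_columns: Optional[Sequence[str]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Longitudinal change of a texture summary between first and last scan.

    ``features`` has one row per ROI with ``patient_id``, ``scan_index``,
    ``label`` and feature columns.  The tracked quantity defaults to the
    mean of the detail-scale standard-deviation features
    (columns ``s1_w*_stddev``).  Per patient, the quantity is averaged over
    each scan's ROIs; delta = last scan - first scan.  Patients with a
    single scan are excluded with a logged warning.

    Returns (per_patient, class_summary) data frames; the summary has the
    per-class mean delta with a normal-approximation 95% CI.
    """
    if feature_columns is None:
        feature_columns = [
            c for c in features.columns if c.startswith("s1_w") and c.endswith("_stddev")
        ]
    if not feature_columns:
        raise ValueError("no feature columns to track")
    df = features.copy()
    df["_track"] = df[list(feature_columns)].mean(axis=1)

    rows = []
    for pid, grp in df.groupby("patient_id", sort=True):
        scans = grp.groupby("scan_index", sort=True)["_track"].mean()
        if len(scans) < 2:
            logger.warning("patient %s has a single scan; excluded from change analysis", pid)
            continue
        first, last = float(scans.iloc[0]), float(scans.iloc[-1])
        rows.append(
            {
                "patient_id": pid,
                "label": grp["label"].iloc[0],
                "first_value": first,
                "last_value": last,
                "delta": last - first,
            }
        )
    per_patient = pd.DataFrame(rows)
    if per_patient.empty:
        raise ValueError("no patient has at least two scans")

    summaries = []
    for lab, grp in per_patient.groupby("label"):
        deltas = grp["delta"].to_numpy()
        mean = float(deltas.mean())
        se = float(deltas.std(ddof=1) / np.sqrt(len(deltas))) if len(deltas) > 1 else float("nan")
        summaries.append(
            {
                "label": lab,
                "n": len(deltas),
                "mean_delta": mean,
                "se": se,
                "ci_low": mean - 1.96 * se if np.isfinite(se) else float("nan"),
                "ci_high": mean + 1.96 * se if np.isfinite(se) else float("nan"),
            }
        )
    return per_patient, pd.DataFrame(summaries)
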