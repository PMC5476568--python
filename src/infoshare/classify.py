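"""Patient-versus-control classification from connectivity and test scores.

Feature sets follow the three-model comparison of the study design:
neuropsychological variables (NPV) alone, six connectivity variables (CNV)
alone, or both.  The two first CNVs are distance-range means of the frontal
seed ROIs; the remaining four are mean connectivities between the electrode
sets derived from the two-stage seed analysis.

The classifier protocol is a repeated random holdout: each repeat trains a
linear support-vector machine on seven randomly chosen subjects per group
(features z-scored by training statistics) and classifies the remaining
subjects.  Sensitivity is the correctly classified patient fraction,
specificity the control fraction; the "classification rate" reported is the
mean balanced accuracy across repeats (test sets are imbalanced), with the
raw accuracy alongside.  ROC curves pool the decision scores of all held-out
subjects across repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn import metrics
from sklearn.svm import SVC

from .montage import Montage
from .topo import range_mean, set_pair_mean

__all__ = [
    "FeatureSpec",
    "ClassificationReport",
    "build_features",
    "svm_repeated_holdout",
    "roc_auc",
    "hotelling_t2",
]

PATIENT = "patient"


@dataclass(frozen=True)
class FeatureSpec:
    """Definitions of the six connectivity variables and the NPV columns.

    ``range_features`` are ``(name, roi, d_min, d_max)`` distance-range
    means; ``set_features`` are ``(name, set_a, set_b)`` electrode-set mean
    connectivities.  CNV mode requires exactly six variables in total.
    """

    range_features: tuple[tuple[str, str, float, float], ...] = ()
    set_features: tuple[tuple[str, tuple[str, ...], tuple[str, ...]], ...] = ()
    npv_columns: tuple[str, ...] = ()

    @property
    def n_cnv(self) -> int:
        return len(self.range_features) + len(self.set_features)


def build_features(
    npv: pd.DataFrame,
    connectivity: dict[str, np.ndarray] | None,
    montage: Montage | None,
    spec: FeatureSpec,
    mode: str,
) -> pd.DataFrame:
    """Per-subject feature table for one of the modes NPV / CNV / BOTH."""
    mode = mode.upper()
    if mode not in ("NPV", "CNV", "BOTH"):
        raise ValueError(f"unknown mode {mode!r}")
    blocks: list[pd.DataFrame] = []
    if mode in ("NPV", "BOTH"):
        missing = [c for c in spec.npv_columns if c not in npv.columns]
        if missing:
            raise ValueError(f"missing NPV columns {missing}")
        blocks.append(npv[list(spec.npv_columns)])
    if mode in ("CNV", "BOTH"):
        if spec.n_cnv != 6:
            raise ValueError(
                f"CNV mode requires exactly 6 connectivity variables, "
                f"got {spec.n_cnv}"
            )
        if connectivity is None or montage is None:
            raise ValueError("CNV mode needs connectivity matrices")
        subjects = npv.index
        cols: dict[str, list[float]] = {}
        for name, roi, d_min, d_max in spec.range_features:
            cols[name] = [
                range_mean(connectivity[s], montage, roi, d_min, d_max)
                for s in subjects
            ]
        for name, set_a, set_b in spec.set_features:
            cols[name] = [
                set_pair_mean(connectivity[s], montage, list(set_a), list(set_b))
                for s in subjects
            ]
        blocks.append(pd.DataFrame(cols, index=subjects))
    return pd.concat(blocks, axis=1)


@dataclass
class ClassificationReport:
    """Outcome of the repeated-holdout SVM protocol."""

    per_repeat: pd.DataFrame  # sensitivity, specificity, accuracy, balanced
    pooled_scores: np.ndarray  # decision scores of all held-out subjects
    pooled_labels: np.ndarray  # matching true labels (1 = patient)
    n_train_per_group: int
    summary: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        pr = self.per_repeat
        self.summary = {
            "sensitivity_mean": float(pr["sensitivity"].mean()),
            "sensitivity_sd": float(pr["sensitivity"].std(ddof=1)),
            "specificity_mean": float(pr["specificity"].mean()),
            "specificity_sd": float(pr["specificity"].std(ddof=1)),
            "accuracy_mean": float(pr["accuracy"].mean()),
            "balanced_accuracy_mean": float(pr["balanced_accuracy"].mean()),
            "n_repeats": int(len(pr)),
        }

    @property
    def classification_rate(self) -> float:
        """Mean balanced accuracy across repeats, in [0, 1]."""
        return self.summary["balanced_accuracy_mean"]


def svm_repeated_holdout(
    features: pd.DataFrame | np.ndarray,
    labels,
    n_train_per_group: int = 7,
    n_repeats: int = 1000,
    seed: int | None = None,
    C: float = 1.0,
) -> ClassificationReport:
    """Repeated random-holdout linear SVM.

    Each repeat draws ``n_train_per_group`` subjects per group for training
    (z-scoring features by the training statistics), fits ``SVC(kernel=
    'linear')`` and classifies every held-out subject.  Reproducible given
    ``seed``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray([1 if g == PATIENT else 0 for g in labels])
    if X.shape[0] != y.size:
        raise ValueError("features and labels disagree on subject count")
    pat_idx = np.flatnonzero(y == 1)
    ctl_idx = np.flatnonzero(y == 0)
    if len(pat_idx) <= n_train_per_group or len(ctl_idx) <= n_train_per_group:
        raise ValueError(
            f"each group needs more than {n_train_per_group} subjects"
        )
    rng = np.random.default_rng(seed)
    rows = []
    scores_all: list[np.ndarray] = []
    labels_all: list[np.ndarray] = []
    for _ in range(n_repeats):
        tr = np.concatenate([
            rng.choice(pat_idx, n_train_per_group, replace=False),
            rng.choice(ctl_idx, n_train_per_group, replace=False),
        ])
        te = np.setdiff1d(np.arange(y.size), tr)
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        clf = SVC(kernel="linear", C=C)
        clf.fit((X[tr] - mu) / sd, y[tr])
        z = (X[te] - mu) / sd
        pred = clf.predict(z)
        score = clf.decision_function(z)
        te_pat = y[te] == 1
        sens = float((pred[te_pat] == 1).mean())
        spec = float((pred[~te_pat] == 0).mean())
        rows.append(
            {"sensitivity": sens, "specificity": spec,
             "accuracy": float((pred == y[te]).mean()),
             "balanced_accuracy": (sens + spec) / 2.0}
        )
        scores_all.append(score)
        labels_all.append(y[te])
    return ClassificationReport(
        per_repeat=pd.DataFrame(rows),
        pooled_scores=np.concatenate(scores_all),
        pooled_labels=np.concatenate(labels_all),
        n_train_per_group=n_train_per_group,
    )


def roc_auc(report: ClassificationReport) -> tuple[pd.DataFrame, float]:
    """ROC curve and trapezoidal AUC over the pooled held-out scores."""
    y = report.pooled_labels
    if len(np.unique(y)) < 2:
        raise ValueError("pooled scores contain a single class")
    fpr, tpr, thr = metrics.roc_curve(y, report.pooled_scores)
    auc = float(metrics.auc(fpr, tpr))
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return curve, auc


def hotelling_t2(pairs_a, pairs_b) -> tuple[float, float, float]:
    """Two-sample Hotelling's T-squared test on bivariate samples.

    Used to compare the (sensitivity, specificity) pairs of two
    classification models.  Returns ``(T2, F, p)`` with the F
    approximation; note that holdout repeats are resamples of the same
    cohort, so the nominal p-value is descriptive rather than strictly
    valid.
    """
    a = np.asarray(pairs_a, dtype=float)
    b = np.asarray(pairs_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("samples must be 2-D with matching dimension")
    k = a.shape[1]
    if k < 2:
        raise ValueError("Hotelling's T2 needs multivariate input")
    na, nb = a.shape[0], b.shape[0]
    if na < 3 or nb < 3:
        raise ValueError("need at least 3 observations per sample")
    diff = a.mean(axis=0) - b.mean(axis=0)
    sa = np.cov(a, rowvar=False)
    sb = np.cov(b, rowvar=False)
    pooled = ((na - 1) * sa + (nb - 1) * sb) / (na + nb - 2)
    try:
        inv = np.linalg.inv(pooled)
    except np.linalg.LinAlgError:
        raise ValueError("singular pooled covariance") from None
    t2 = float(na * nb / (na + nb) * diff @ inv @ diff)
    df2 = na + nb - 1 - k
    if df2 <= 0:
        raise ValueError("too few observations for the F approximation")
    f = t2 * df2 / ((na + nb - 2) * k)
    p = float(sps.f.sf(f, k, df2))
    return t2, float(f), p
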