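"""Replicate-aware model validation.

Cross-validation uses contiguous blocks after a subject-level shuffle, so
all replicate spectra of one subject always share a fold — replicate
leakage between calibration and validation would otherwise make the CV
error wildly optimistic.  Component counts are selected by the minimum
cross-validated error; classification thresholds come from a Bayesian
treatment of per-class Gaussian fits to the calibration predictions; and
model significance is assessed by a subject-level permutation test.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .dataset import SpectraDataset
from .models import OPLS, ColumnScaler, encode_classes

UNASSIGNED = "Unassigned"


# ----------------------------------------------------------------------
# CV plan


@dataclasses.dataclass
class CVPlan:
    fold_of_sample: np.ndarray
    n_folds: int
    subjects_per_block: int
    block_size_samples: int
    seed: int


def block_geometry(
    n_samples: int, replicates: int, n_folds: int
) -> tuple[int, int]:
    """Contiguous-block geometry for replicate-grouped n-fold CV.

    subjects per block = ceil(N / (r · n_folds)); block size in samples is
    that times r.  E.g. 265 triplicate samples in 7 folds give blocks of
    13 subjects x 3 = 39 samples.
    """
    if n_folds < 1 or replicates < 1 or n_samples < 1:
        raise ValueError("n_samples, replicates and n_folds must be positive")
    subjects_per_block = math.ceil(n_samples / (replicates * n_folds))
    return subjects_per_block, subjects_per_block * replicates


def make_cv_plan(samples: pd.DataFrame, n_folds: int, seed: int = 0) -> CVPlan:
    """Assign whole subjects to contiguous CV blocks after a seeded shuffle.

    Every replicate of a subject lands in the same fold.  Requires an equal
    replicate count per subject (the design assumes triplicates); the last
    block may hold fewer subjects.
    """
    counts = samples.groupby("subject_id").size()
    if counts.nunique() != 1:
        raise ValueError("all subjects must have the same replicate count")
    r = int(counts.iloc[0])
    subjects = samples["subject_id"].drop_duplicates().to_numpy()
    if n_folds > subjects.size:
        raise ValueError("more folds than subjects")

    spb, block_size = block_geometry(len(samples), r, n_folds)
    rng = np.random.default_rng(seed)
    shuffled = subjects[rng.permutation(subjects.size)]
    fold_of_subject = {
        subj: i // spb for i, subj in enumerate(shuffled)
    }
    fold_of_sample = samples["subject_id"].map(fold_of_subject).to_numpy()
    return CVPlan(
        fold_of_sample=fold_of_sample,
        n_folds=int(fold_of_sample.max()) + 1,
        subjects_per_block=spb,
        block_size_samples=block_size,
        seed=seed,
    )


def check_no_subject_leakage(samples: pd.DataFrame, plan: CVPlan) -> None:
    """Raise if any subject straddles folds (asserted on every CV run)."""
    df = samples.assign(fold=plan.fold_of_sample)
    split = df.groupby("subject_id")["fold"].nunique()
    if (split > 1).any():
        raise RuntimeError(
            f"subjects split across folds: {split[split > 1].index.tolist()}"
        )


# ----------------------------------------------------------------------
# cross-validated model selection


@dataclasses.dataclass
class FitMetrics:
    """Calibration/CV error per orthogonal-component count (0..max)."""

    components: list[int]
    rmsec: np.ndarray
    rmsecv: np.ndarray
    chosen_components: int
    rmsep: np.ndarray | None = None


def _cv_predictions(
    X: np.ndarray,
    y: np.ndarray,
    labels: np.ndarray,
    plan: CVPlan,
    scaling_method: str,
    n_orth: int,
) -> np.ndarray:
    """Out-of-fold OPLS predictions; scaling refitted inside each fold."""
    yhat = np.empty_like(y, dtype=float)
    for fold in range(plan.n_folds):
        test = plan.fold_of_sample == fold
        train = ~test
        if len(set(labels[train])) < 2:
            raise ValueError(f"training split of fold {fold} lacks a class")
        scaler = ColumnScaler(method=scaling_method).fit(
            X[train], labels[train] if scaling_method == "class_centroid" else None
        )
        model = OPLS(n_orthogonal=n_orth).fit(scaler.transform(X[train]), y[train])
        yhat[test] = model.predict(scaler.transform(X[test]))
    return yhat


def cross_validate(
    ds: SpectraDataset,
    plan: CVPlan,
    scaling_method: str = "auto",
    max_orth: int = 3,
) -> FitMetrics:
    """RMSEC/RMSECV over orthogonal-component counts 0..max_orth.

    The chosen count is the smallest within 1% of the minimum RMSECV
    (parsimony tie-break).
    """
    if plan.fold_of_sample.shape[0] != ds.n_samples:
        raise ValueError("CV plan does not cover the dataset")
    check_no_subject_leakage(ds.samples, plan)
    labels = ds.class_labels
    y, _ = encode_classes(labels)
    X = ds.intensities

    ks = list(range(max_orth + 1))
    rmsec = np.empty(len(ks))
    rmsecv = np.empty(len(ks))
    for i, k in enumerate(ks):
        scaler = ColumnScaler(method=scaling_method).fit(
            X, labels if scaling_method == "class_centroid" else None
        )
        full = OPLS(n_orthogonal=k).fit(scaler.transform(X), y)
        rmsec[i] = float(np.sqrt(np.mean((full.fitted_values_ - y) ** 2)))
        yhat = _cv_predictions(X, y, labels, plan, scaling_method, k)
        rmsecv[i] = float(np.sqrt(np.mean((yhat - y) ** 2)))

    best = rmsecv.min()
    chosen = next(k for k, v in zip(ks, rmsecv) if v <= best * 1.01)
    return FitMetrics(
        components=ks, rmsec=rmsec, rmsecv=rmsecv, chosen_components=chosen
    )


# ----------------------------------------------------------------------
# Bayesian thresholds and confusion matrix


@dataclasses.dataclass
class ThresholdModel:
    class_stats: dict[str, tuple[float, float]]  # label -> (mean, sd) of yhat
    priors: dict[str, float]
    thresholds: dict[str, float]  # label -> threshold for that class model
    classes: tuple[str, str]  # (negative, positive)
    fallback_used: bool = False


def _equal_posterior_root(
    m0: float, s0: float, pi0: float, m1: float, s1: float, pi1: float
) -> float | None:
    """ŷ where pi1·N(ŷ; m1, s1) = pi0·N(ŷ; m0, s0), between the means."""
    lo, hi = sorted((m0, m1))
    const = math.log(pi1 * s0 / (pi0 * s1))
    a = 0.5 * (1.0 / s0**2 - 1.0 / s1**2)
    b = m1 / s1**2 - m0 / s0**2
    c = 0.5 * (m0**2 / s0**2 - m1**2 / s1**2) + const
    if abs(a) < 1e-15:
        if b == 0:
            return None
        root = -c / b
        return root if lo <= root <= hi else None
    disc = b**2 - 4 * a * c
    if disc < 0:
        return None
    roots = [(-b + s * math.sqrt(disc)) / (2 * a) for s in (-1.0, 1.0)]
    inside = [r for r in roots if lo <= r <= hi]
    return inside[0] if inside else None


def bayesian_thresholds(
    y_hat_cal: np.ndarray, labels, prior: str = "proportions"
) -> ThresholdModel:
    """Per-class classification thresholds from Gaussian posterior equality.

    A Gaussian is fitted to each class's calibration predictions; a class
    model's threshold is the prediction value where the two posterior
    probabilities are equal.  Under {0,1} coding the two class models see
    mirrored predictions, so the two thresholds are complementary (they sum
    to 1) — matching the kind of asymmetric pair unequal class sizes
    produce.  If no root lies between the class means the midpoint is used
    and flagged.
    """
    y_hat_cal = np.asarray(y_hat_cal, dtype=float)
    y, (neg, pos) = encode_classes(labels)
    pred_pos = y_hat_cal[y == 1]
    pred_neg = y_hat_cal[y == 0]
    if len(pred_pos) < 2 or len(pred_neg) < 2:
        raise ValueError("need at least two calibration samples per class")
    m1, s1 = float(pred_pos.mean()), float(pred_pos.std(ddof=1))
    m0, s0 = float(pred_neg.mean()), float(pred_neg.std(ddof=1))
    if s0 == 0 or s1 == 0:
        raise ValueError("per-class prediction spread must be positive")
    n = y_hat_cal.size
    if prior == "proportions":
        pi1, pi0 = len(pred_pos) / n, len(pred_neg) / n
    elif prior == "equal":
        pi1 = pi0 = 0.5
    else:
        raise ValueError(f"unknown prior {prior!r}")

    root = _equal_posterior_root(m0, s0, pi0, m1, s1, pi1)
    fallback = root is None
    theta_pos = 0.5 * (m0 + m1) if fallback else float(root)
    return ThresholdModel(
        class_stats={pos: (m1, s1), neg: (m0, s0)},
        priors={pos: pi1, neg: pi0},
        thresholds={pos: theta_pos, neg: 1.0 - theta_pos},
        classes=(neg, pos),
        fallback_used=fallback,
    )


@dataclasses.dataclass
class ConfusionMatrix:
    counts: pd.DataFrame  # predicted (incl. Unassigned) x actual
    accuracy: float


def classify_and_score(
    y_hat: np.ndarray, thresholds: ThresholdModel, actual
) -> ConfusionMatrix:
    """Two-sided class assignment and the resulting confusion matrix.

    The positive-class rule fires when ŷ >= its threshold; the
    negative-class rule when 1 − ŷ >= its own threshold.  Samples firing
    neither or both rules are 'Unassigned'.  Accuracy counts correctly
    assigned samples over all samples (misclassified and unassigned both
    count against it).
    """
    y_hat = np.asarray(y_hat, dtype=float)
    actual = np.asarray(actual)
    if y_hat.size != actual.size:
        raise ValueError("prediction/label length mismatch")
    neg, pos = thresholds.classes
    pos_fire = y_hat >= thresholds.thresholds[pos]
    neg_fire = (1.0 - y_hat) >= thresholds.thresholds[neg]
    predicted = np.where(
        pos_fire & ~neg_fire, pos, np.where(neg_fire & ~pos_fire, neg, UNASSIGNED)
    )
    rows = [pos, neg, UNASSIGNED]
    cols = [pos, neg]
    counts = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for pr, ac in zip(predicted, actual):
        counts.loc[pr, ac] += 1
    accuracy = float((predicted == actual).sum() / actual.size)
    return ConfusionMatrix(counts=counts, accuracy=accuracy)


# ----------------------------------------------------------------------
# permutation test


@dataclasses.dataclass
class PermutationResult:
    n_iterations: int
    observed: float
    null_statistics: np.ndarray
    p_value: float
    statistic: str = "cv_accuracy"


def _cv_statistic(
    X: np.ndarray,
    labels: np.ndarray,
    samples: pd.DataFrame,
    plan: CVPlan,
    scaling_method: str,
    n_orth: int,
    statistic: str,
) -> float:
    y, _ = encode_classes(labels)
    yhat = _cv_predictions(X, y, labels, plan, scaling_method, n_orth)
    if statistic == "cv_accuracy":
        return float(((yhat >= 0.5) == (y == 1)).mean())
    if statistic == "rmsecv":
        return float(np.sqrt(np.mean((yhat - y) ** 2)))
    raise ValueError(f"unknown statistic {statistic!r}")


def permutation_test(
    ds: SpectraDataset,
    plan_seed: int = 0,
    n_folds: int = 7,
    scaling_method: str = "auto",
    n_orth: int = 1,
    n_iter: int = 200,
    seed: int = 0,
    statistic: str = "cv_accuracy",
) -> PermutationResult:
    """Subject-level label-permutation test of the cross-validated model.

    Class labels are permuted across subjects (replicates move together),
    the full CV pipeline is re-run per iteration, and the empirical p-value
    is (1 + #{null at least as good as observed}) / (n_iter + 1).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    samples = ds.samples
    subjects = samples["subject_id"].drop_duplicates().to_numpy()
    subj_label = (
        samples.drop_duplicates("subject_id").set_index("subject_id")["class_label"]
    )
    plan = make_cv_plan(samples, n_folds, seed=plan_seed)
    X = ds.intensities

    observed = _cv_statistic(
        X, ds.class_labels, samples, plan, scaling_method, n_orth, statistic
    )
    rng = np.random.default_rng(seed)
    base = subj_label.loc[subjects].to_numpy()
    null = np.empty(n_iter)
    for it in range(n_iter):
        perm = base[rng.permutation(base.size)]
        lab_map = dict(zip(subjects, perm))
        labels = samples["subject_id"].map(lab_map).to_numpy()
        null[it] = _cv_statistic(
            X, labels, samples, plan, scaling_method, n_orth, statistic
        )
    if statistic == "rmsecv":  # smaller is better
        better = null <= observed
    else:
        better = null >= observed
    p = (1 + int(better.sum())) / (n_iter + 1)
    return PermutationResult(
        n_iterations=n_iter,
        observed=observed,
        null_statistics=null,
        p_value=p,
        statistic=statistic,
    )
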