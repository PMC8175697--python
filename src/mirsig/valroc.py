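"""Independent-cohort validation: scores, AUC + DeLong CI, ROC, Youden cutoff.

A designed signature is validated on a cohort that was normalized separately
from the design cohort.  Each subject's score is the ensemble cancer
probability — the mean, over the design repeats' forests, of the fraction of
trees voting "cancer" (with fully grown trees the forest's predicted class
probability equals the tree-vote fraction).  Discrimination is summarized by
the Mann-Whitney AUC with a DeLong confidence interval, and an operating
point is fixed at the Youden-index-optimal cutoff (maximizing sensitivity +
specificity - 1; ties resolved toward the higher cutoff, favoring
specificity).  A signature using an miRNA that the validation cohort's panel
never measured cannot be scored there and is discarded with a recorded
reason rather than an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._common import align_labels, binarize
from .io_model import NormalizedMatrix, ValidationError

logger = logging.getLogger(__name__)

Z_975 = float(stats.norm.ppf(0.975))


def _split_scores(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind in "OUS":
        y = binarize(align_labels(range(len(scores)), labels))
    else:
        y = labels.astype(int)
    pos = scores[y == 1]
    neg = scores[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both classes must be present to compute an AUC")
    return pos, neg


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(random cancer score > random healthy score),
    ties counted 1/2."""
    pos, neg = _split_scores(scores, labels)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def auc_ci(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """DeLong variance-based confidence interval, clipped to [0, 1].

    With every score tied the variance is undefined; a maximally wide
    interval is returned with a warning.
    """
    pos, neg = _split_scores(scores, labels)
    if len(pos) < 2 or len(neg) < 2:
        raise ValidationError("DeLong interval needs >= 2 samples per class")
    if np.ptp(np.concatenate([pos, neg])) == 0:
        logger.warning("all scores tied; AUC interval is uninformative")
        return (0.0, 1.0)
    m, n = len(pos), len(neg)
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    # DeLong structural components: per-positive and per-negative placements
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    point = float(np.mean(v10))
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    half = z * np.sqrt(max(var, 0.0))
    return (max(0.0, point - half), min(1.0, point + half))


def _thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints between sorted distinct scores, with -inf/+inf ends."""
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate([[-np.inf], mids, [np.inf]])


def roc_curve(scores, labels) -> np.ndarray:
    """ROC points (1 - specificity, sensitivity), one per threshold, ordered
    from (0, 0) to (1, 1).  Classification rule: score >= threshold => cancer."""
    pos, neg = _split_scores(scores, labels)
    points = []
    for t in _thresholds(np.concatenate([pos, neg]))[::-1]:
        sens = float(np.mean(pos >= t))
        fpr = float(np.mean(neg >= t))
        points.append((fpr, sens))
    return np.asarray(points)


def trapezoidal_auc(roc_points: np.ndarray) -> float:
    return float(np.trapezoid(roc_points[:, 1], roc_points[:, 0]))


def youden_cutoff(scores, labels) -> tuple[float, float, float]:
    """Cutoff maximizing J = sensitivity + specificity - 1.

    Candidates are the midpoints between distinct scores plus the two
    unbounded ends; ties in J are resolved toward the highest cutoff.
    Returns (cutoff, sensitivity, specificity) at the optimum.
    """
    pos, neg = _split_scores(scores, labels)
    best = None
    for t in _thresholds(np.concatenate([pos, neg])):
        sens = float(np.mean(pos >= t))
        spec = float(np.mean(neg < t))
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and t > best[1]):
            best = (j, float(t), sens, spec)
    return best[1], best[2], best[3]


@dataclass
class DiscardEvent:
    """A signature that cannot be scored on a cohort, and why."""

    signature_name: str
    cohort_id: str
    missing_mirnas: tuple[str, ...]

    @property
    def reason(self) -> str:
        return (
            f"signature {self.signature_name!r} discarded on cohort "
            f"{self.cohort_id!r}: miRNA(s) not measured: {sorted(self.missing_mirnas)}"
        )


@dataclass
class SignaturePerformance:
    """Validation record: AUC, CI, Youden operating point, per-subject scores."""

    signature_name: str
    n_mirnas: int
    validation_auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    cohort_id: str = ""
    scores: pd.Series | None = field(default=None, repr=False)
    klass_labels: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for v, nm in (
            (self.validation_auc, "AUC"),
            (self.sensitivity, "sensitivity"),
            (self.specificity, "specificity"),
        ):
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{nm} outside [0, 1]: {v}")
        if not self.ci_low <= self.validation_auc <= self.ci_high:
            raise ValidationError(
                f"CI [{self.ci_low}, {self.ci_high}] does not bracket AUC "
                f"{self.validation_auc}"
            )


def predict_ensemble(ens, nm: NormalizedMatrix) -> pd.Series | DiscardEvent:
    """Per-sample ensemble cancer score in [0, 1].

    Returns a :class:`DiscardEvent` when the signature uses an miRNA the
    cohort never measured (panel mismatch).  Samples with missing values in
    the signature's columns cannot be scored and are dropped with a warning.
    """
    features = list(ens.feature_order)
    missing = [m for m in features if m not in set(nm.mirna_ids)]
    if missing:
        event = DiscardEvent(ens.signature.name, nm.source_dataset_id, tuple(missing))
        logger.info(event.reason)
        return event
    frame = nm.frame.loc[:, features]
    ok = ~frame.isna().any(axis=1)
    if (~ok).any():
        logger.warning(
            "%d sample(s) with missing values in signature %s columns dropped",
            int((~ok).sum()), ens.signature.name,
        )
    X = frame.loc[ok].to_numpy()
    total = np.zeros(len(X))
    for forest in ens.models:
        proba = forest.predict_proba(X)
        total += proba[:, list(forest.classes_).index(1)]
    return pd.Series(total / len(ens.models), index=frame.index[ok], name="score")


def validate_signature(
    ens, nm_validation: NormalizedMatrix, labels, cohort_id: str = "", level: float = 0.95
) -> SignaturePerformance | DiscardEvent:
    """Score a design ensemble on an independently normalized cohort and
    compose AUC, DeLong CI and the Youden operating point into one record."""
    scores = predict_ensemble(ens, nm_validation)
    if isinstance(scores, DiscardEvent):
        if not scores.cohort_id:
            scores.cohort_id = cohort_id
        return scores
    y_labels = align_labels(scores.index, labels)
    point = auc(scores.to_numpy(), binarize(y_labels))
    lo, hi = auc_ci(scores.to_numpy(), binarize(y_labels), level=level)
    lo, hi = min(lo, point), max(hi, point)
    cut, sens, spec = youden_cutoff(scores.to_numpy(), binarize(y_labels))
    return SignaturePerformance(
        signature_name=ens.signature.name,
        n_mirnas=len(ens.signature),
        validation_auc=point,
        ci_low=lo,
        ci_high=hi,
        cutoff=cut,
        sensitivity=sens,
        specificity=spec,
        cohort_id=cohort_id or nm_validation.source_dataset_id,
        scores=scores,
        klass_labels=pd.Series(y_labels, index=scores.index),
    )
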