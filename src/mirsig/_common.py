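"""Shared helpers: label alignment and deterministic forest construction."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .io_model import CLASS_LABELS, ForestConfig, ValidationError

POSITIVE_CLASS = "cancer"


def align_labels(sample_ids: Sequence[str], labels) -> np.ndarray:
    """Return labels as an array aligned to ``sample_ids``.

    ``labels`` may be a mapping/Series keyed by sample id or a sequence in
    sample order.  Labels must come from the declared class set.
    """
    if isinstance(labels, (Mapping, pd.Series)):
        try:
            arr = np.asarray([labels[s] for s in sample_ids], dtype=object)
        except KeyError as e:
            raise ValidationError(f"no label for sample {e.args[0]!r}") from e
    else:
        arr = np.asarray(list(labels), dtype=object)
        if len(arr) != len(sample_ids):
            raise ValidationError(
                f"{len(arr)} labels for {len(sample_ids)} samples"
            )
    bad = set(arr) - set(CLASS_LABELS)
    if bad:
        raise ValidationError(f"unknown class labels {sorted(bad)}")
    return arr


def binarize(labels: np.ndarray) -> np.ndarray:
    """1 for the positive (cancer) class, 0 otherwise."""
    return (labels == POSITIVE_CLASS).astype(int)


def require_both_classes(y: np.ndarray, min_per_class: int = 1) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < min_per_class:
        raise ValidationError(
            f"need >= {min_per_class} samples of each class, got "
            f"{dict(zip(classes.tolist(), counts.tolist()))}"
        )


def build_forest(cfg: ForestConfig, n_features: int, seed: int) -> RandomForestClassifier:
    """A forest with the configured tree count and mtry = mtry_rule(p)."""
    return RandomForestClassifier(
        n_estimators=cfg.ntree,
        max_features=min(max(1, cfg.mtry_rule(n_features)), n_features),
        random_state=int(seed) % (2**32),
        n_jobs=1,
    )


def stratified_indices(
    y: np.ndarray, rng: np.random.Generator, fraction: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Split indices per class: a ``fraction`` draw without replacement
    (train/test split) or, with ``fraction=None``, a same-size bootstrap
    (in-bag/out-of-bag).  Class proportions are preserved."""
    take, rest = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if fraction is None:
            bag = rng.choice(idx, size=len(idx), replace=True)
            take.append(bag)
            rest.append(np.setdiff1d(idx, bag))
        else:
            n_train = int(round(fraction * len(idx)))
            n_train = min(max(n_train, 1), len(idx) - 1)
            perm = rng.permutation(idx)
            take.append(perm[:n_train])
            rest.append(perm[n_train:])
    return np.sort(np.concatenate(take)), np.sort(np.concatenate(rest))
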