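"""Exhaustive signature enumeration and design-cohort performance estimation.

Every non-empty subset of the selected feature pool is a candidate signature
(2^k - 1 of them).  Each is scored by Monte-Carlo cross-validation: the
design cohort is split ``n_design_repeats`` times (default 50) into a
stratified 90% training / 10% test partition, one forest (ntree, mtry =
floor(sqrt(signature size))) is fitted per split on the signature's columns,
and the mean test AUC over splits is the signature's design performance.
The same splits are reused for every signature so that scores are
comparable.  Ten-fold stratified CV is available as an alternative scheme.
"""

from __future__ import annotations

import itertools
import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from ._common import align_labels, binarize, build_forest, require_both_classes, stratified_indices
from .io_model import ForestConfig, NormalizedMatrix, Signature, ValidationError
from .valroc import auc as mann_whitney_auc

logger = logging.getLogger(__name__)

MAX_POOL = 25  # 2^25 - 1 subsets is already past desk scale


def enumerate_signatures(pool: list[str], allow_large: bool = False) -> list[Signature]:
    """All non-empty subsets of the pool, ordered by size then name tuple.

    ``allow_large`` overrides the |pool| <= 25 combinatorial guard.
    """
    if not pool:
        raise ValidationError("empty feature pool")
    if len(set(pool)) != len(pool):
        raise ValidationError("duplicate names in feature pool")
    if len(pool) > MAX_POOL and not allow_large:
        raise ValidationError(
            f"pool of {len(pool)} would enumerate {2 ** len(pool) - 1} signatures; "
            "pass allow_large=True to override"
        )
    ordered = sorted(pool)
    out: list[Signature] = []
    i = 1
    for size in range(1, len(ordered) + 1):
        for combo in itertools.combinations(ordered, size):
            out.append(Signature(f"sig_{i:06d}", frozenset(combo)))
            i += 1
    return out


@dataclass
class DesignSplit:
    """One stratified train/test partition, stored by sample id for replay."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]


def make_design_splits(
    sample_ids: list[str], labels, cfg: ForestConfig
) -> list[DesignSplit]:
    """The shared Monte-Carlo splits: ``n_design_repeats`` stratified draws of
    ``train_fraction`` of each class."""
    y_labels = align_labels(sample_ids, labels)
    require_both_classes(binarize(y_labels), min_per_class=2)
    y = binarize(y_labels)
    rng = np.random.default_rng(cfg.seed)
    ids = np.asarray(sample_ids)
    splits = []
    for _ in range(cfg.n_design_repeats):
        train, test = stratified_indices(y, rng, fraction=cfg.train_fraction)
        splits.append(DesignSplit(tuple(ids[train]), tuple(ids[test])))
    return splits


def make_kfold_splits(sample_ids: list[str], labels, n_folds: int = 10, seed: int = 0) -> list[DesignSplit]:
    """Stratified k-fold alternative to the Monte-Carlo splits."""
    y = binarize(align_labels(sample_ids, labels))
    ids = np.asarray(sample_ids)
    kf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [
        DesignSplit(tuple(ids[tr]), tuple(ids[te])) for tr, te in kf.split(ids, y)
    ]


@dataclass
class ModelEnsemble:
    """The fitted forests of one signature, one per design repeat."""

    signature: Signature
    feature_order: tuple[str, ...]
    models: list[RandomForestClassifier]
    splits: list[DesignSplit]
    cfg: ForestConfig
    design_auc_mean: float
    per_split_auc: list[float] = field(default_factory=list)
    n_skipped_splits: int = 0

    @property
    def name(self) -> str:
        return self.signature.name


def evaluate_signature_design(
    sig: Signature,
    nm: NormalizedMatrix,
    labels,
    cfg: ForestConfig,
    splits: list[DesignSplit] | None = None,
) -> ModelEnsemble:
    """Fit one forest per design split on the signature's columns and average
    the test AUCs.  Splits default to a fresh seeded set; pass the output of
    :func:`make_design_splits` to share partitions across signatures."""
    missing = sig.mirna_ids - set(nm.mirna_ids)
    if missing:
        raise ValidationError(
            f"signature {sig.name!r} uses miRNA(s) absent from the matrix: "
            f"{sorted(missing)}"
        )
    features = sig.sorted_members
    frame = nm.frame.loc[:, list(features)]
    if frame.isna().any().any():
        bad = [m for m in features if frame[m].isna().any()]
        raise ValidationError(
            f"signature {sig.name!r}: missing delta-Cq values in {bad}"
        )
    y_all = pd.Series(binarize(align_labels(nm.sample_ids, labels)), index=nm.sample_ids)
    if splits is None:
        splits = make_design_splits(nm.sample_ids, labels, cfg)

    sig_hash = zlib.crc32("+".join(features).encode())  # stable across runs
    seed_base = np.random.default_rng((cfg.seed, sig_hash)).integers(2**31)
    models, aucs, skipped = [], [], 0
    for i, split in enumerate(splits):
        X_tr = frame.loc[list(split.train_ids)].to_numpy()
        y_tr = y_all[list(split.train_ids)].to_numpy()
        X_te = frame.loc[list(split.test_ids)].to_numpy()
        y_te = y_all[list(split.test_ids)].to_numpy()
        forest = build_forest(cfg, len(features), seed=(seed_base + i) % (2**31))
        forest.fit(X_tr, y_tr)
        models.append(forest)
        if len(np.unique(y_te)) < 2:
            skipped += 1
            continue
        scores = forest.predict_proba(X_te)[:, list(forest.classes_).index(1)]
        aucs.append(mann_whitney_auc(scores, y_te))
    if skipped:
        logger.warning(
            "signature %s: %d/%d test partitions single-class, skipped in AUC mean",
            sig.name, skipped, len(splits),
        )
    if not aucs:
        raise ValidationError(f"signature {sig.name!r}: no scorable test partition")
    return ModelEnsemble(
        signature=sig,
        feature_order=features,
        models=models,
        splits=splits,
        cfg=cfg,
        design_auc_mean=float(np.mean(aucs)),
        per_split_auc=[float(a) for a in aucs],
        n_skipped_splits=skipped,
    )


def search_signatures(
    signatures: list[Signature],
    nm: NormalizedMatrix,
    labels,
    cfg: ForestConfig,
) -> list[ModelEnsemble]:
    """Evaluate every candidate signature on one shared set of design splits."""
    splits = make_design_splits(nm.sample_ids, labels, cfg)
    return [
        evaluate_signature_design(sig, nm, labels, cfg, splits=splits)
        for sig in signatures
    ]


def filter_signatures(
    ensembles: list[ModelEnsemble], auc_min: float
) -> list[ModelEnsemble]:
    """Shortlist: design AUC >= auc_min (inclusive), best first; ties by
    smaller signature then name."""
    kept = [e for e in ensembles if e.design_auc_mean >= auc_min]
    return sorted(
        kept, key=lambda e: (-e.design_auc_mean, len(e.signature), e.name)
    )


def shortlist_table(ensembles: list[ModelEnsemble]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": e.name,
                "members": "+".join(e.feature_order),
                "n_mirnas": len(e.signature),
                "design_auc_mean": e.design_auc_mean,
            }
            for e in ensembles
        ],
        columns=["name", "members", "n_mirnas", "design_auc_mean"],
    )
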