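"""Random-forest miRNA ranking with selection-stability quantification.

For each of ``n_fs_partitions`` stratified bootstrap resamples of the design
set, a forest is fitted and two importance measures are recorded per miRNA:
MDA (mean decrease in accuracy — permutation importance evaluated on the
partition's out-of-bag samples) and MDG (mean decrease in Gini — total
impurity decrease).  Importances are averaged over partitions, each column
is ranked (rank 1 = most important, ties broken lexicographically), and the
combined rank orders miRNAs by the mean of their MDA and MDG ranks — raw MDA
and MDG scales are incomparable, their ranks are not.

Stability of the resulting selections across partitions is quantified by the
Kuncheva consistency index (chance-corrected overlap of equal-size
selections) and the mean pairwise Spearman correlation of the full
importance orderings.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._common import align_labels, binarize, build_forest, require_both_classes, stratified_indices
from .io_model import ForestConfig, NormalizedMatrix, ValidationError

logger = logging.getLogger(__name__)

_PERM_REPEATS = 3  # permutations per feature for the OOB accuracy drop


def _oob_permutation_mda(forest, X: np.ndarray, y: np.ndarray, rng) -> np.ndarray:
    """Permutation importance on the out-of-bag samples: mean accuracy drop
    when one feature's column is shuffled.  All features of one repeat are
    scored in a single batched predict call."""
    n, p = X.shape
    base_acc = np.mean(forest.predict(X) == y)
    drops = np.zeros(p)
    for _ in range(_PERM_REPEATS):
        stacked = np.repeat(X[None, :, :], p, axis=0)  # p copies of X
        for j in range(p):
            stacked[j, :, j] = X[rng.permutation(n), j]
        preds = forest.predict(stacked.reshape(p * n, p)).reshape(p, n)
        drops += base_acc - (preds == y).mean(axis=1)
    return drops / _PERM_REPEATS


def _rank_desc(values: pd.Series) -> pd.Series:
    """Dense 1..n ranking, largest value first, ties by name."""
    order = sorted(values.index, key=lambda name: (-values[name], name))
    return pd.Series({name: i + 1 for i, name in enumerate(order)}, dtype=int)[values.index]


def _rank_asc(values: pd.Series) -> pd.Series:
    order = sorted(values.index, key=lambda name: (values[name], name))
    return pd.Series({name: i + 1 for i, name in enumerate(order)}, dtype=int)[values.index]


@dataclass
class FeatureSelectionResult:
    """Averaged importance table plus the per-partition raw importances."""

    table: pd.DataFrame  # index: miRNA; mean_mda, mean_mdg, rank_mda, rank_mdg, combined_rank
    partition_mda: pd.DataFrame  # partitions x miRNAs
    partition_mdg: pd.DataFrame
    cfg: ForestConfig

    def partition_orderings(self) -> list[pd.Series]:
        """Per-partition combined-rank vectors (1 = most important)."""
        out = []
        for i in range(len(self.partition_mda)):
            r_mda = _rank_desc(self.partition_mda.iloc[i])
            r_mdg = _rank_desc(self.partition_mdg.iloc[i])
            out.append(_rank_asc((r_mda + r_mdg) / 2.0))
        return out

    def partition_selections(self, k: int) -> list[frozenset[str]]:
        """Top-k sets per partition, by that partition's combined rank."""
        return [
            frozenset(ordering.index[ordering.to_numpy() <= k])
            for ordering in self.partition_orderings()
        ]


def rf_importance(
    nm: NormalizedMatrix, labels, cfg: ForestConfig
) -> FeatureSelectionResult:
    """Rank features by forest importance over resampling partitions.

    Features with any missing delta-Cq are dropped with a warning — forests
    need complete columns and imputation would fabricate signal.
    """
    y_labels = align_labels(nm.sample_ids, labels)
    require_both_classes(y_labels, min_per_class=2)
    y = binarize(y_labels)

    complete = [m for m in nm.mirna_ids if not nm.frame[m].isna().any()]
    dropped = set(nm.mirna_ids) - set(complete)
    if dropped:
        logger.warning("dropping %d features with missing values", len(dropped))
    if len(complete) < 2:
        raise ValidationError("fewer than 2 complete features available")
    X = nm.frame[complete].to_numpy()

    rng = np.random.default_rng(cfg.seed)
    mda_rows, mdg_rows = [], []
    for part in range(cfg.n_fs_partitions):
        inbag, oob = stratified_indices(y, rng, fraction=None)
        forest = build_forest(cfg, len(complete), seed=rng.integers(2**31))
        forest.fit(X[inbag], y[inbag])
        mdg_rows.append(forest.feature_importances_)
        if len(oob):
            perm_rng = np.random.default_rng(rng.integers(2**31))
            mda_rows.append(_oob_permutation_mda(forest, X[oob], y[oob], perm_rng))
        else:  # pragma: no cover - bootstrap of n>=4 always leaves OOB samples
            mda_rows.append(np.zeros(len(complete)))

    partition_mda = pd.DataFrame(mda_rows, columns=complete)
    partition_mdg = pd.DataFrame(mdg_rows, columns=complete)
    mean_mda = partition_mda.mean(axis=0)
    mean_mdg = partition_mdg.mean(axis=0)
    rank_mda = _rank_desc(mean_mda)
    rank_mdg = _rank_desc(mean_mdg)
    combined = _rank_asc((rank_mda + rank_mdg) / 2.0)
    table = pd.DataFrame(
        {
            "mean_mda": mean_mda,
            "mean_mdg": mean_mdg,
            "rank_mda": rank_mda,
            "rank_mdg": rank_mdg,
            "combined_rank": combined,
        }
    )
    return FeatureSelectionResult(table, partition_mda, partition_mdg, cfg)


@dataclass(frozen=True)
class StabilityReport:
    """Selection stability across resampling partitions."""

    kuncheva_index: float
    spearman_index: float
    n_partitions: int
    selection_size: int


def kuncheva_index(selections: list[frozenset[str]], n_features_total: int) -> float:
    """Chance-corrected pairwise consistency of equal-size selections.

    For two selections of size s from N features with overlap o:
    K = (o - s^2/N) / (s - s^2/N); averaged over all partition pairs.
    1 = identical selections, 0 = chance overlap, negative = avoidance.
    """
    sizes = {len(sel) for sel in selections}
    if len(sizes) != 1:
        raise ValidationError(f"selections differ in size: {sorted(sizes)}")
    s = sizes.pop()
    if s == n_features_total:
        raise ValidationError(
            "selection size equals the feature total; Kuncheva denominator is zero"
        )
    expected = s * s / n_features_total
    denom = s - expected
    vals = [
        (len(a & b) - expected) / denom
        for a, b in itertools.combinations(selections, 2)
    ]
    return float(np.mean(vals))


def spearman_index(orderings: list[pd.Series]) -> float:
    """Mean pairwise Spearman correlation of full importance orderings."""
    vals = []
    for a, b in itertools.combinations(orderings, 2):
        rho = stats.spearmanr(a.to_numpy(), b[a.index].to_numpy()).statistic
        vals.append(rho)
    return float(np.mean(vals))


def stability(
    selections: list[frozenset[str]],
    n_features_total: int,
    orderings: list[pd.Series] | None = None,
) -> StabilityReport:
    """Kuncheva index of the top-k selections and, when the full orderings
    are supplied, the mean pairwise Spearman rank correlation."""
    k = kuncheva_index(selections, n_features_total)
    rho = spearman_index(orderings) if orderings is not None else float("nan")
    return StabilityReport(
        kuncheva_index=k,
        spearman_index=rho,
        n_partitions=len(selections),
        selection_size=len(selections[0]),
    )


def select_features(table: pd.DataFrame, k: int) -> list[str]:
    """Top-k miRNAs by combined rank, best first."""
    if k <= 0:
        raise ValidationError(f"k must be positive, got {k}")
    if k > len(table):
        raise ValidationError(f"k={k} exceeds {len(table)} ranked features")
    ordered = table.sort_values("combined_rank").index
    return list(ordered[:k])


def stability_plateau_k(
    result: FeatureSelectionResult,
    k_min: int = 2,
    k_max: int | None = None,
    tol: float = 0.01,
) -> int:
    """Smallest k at which growing the selection changes Kuncheva by < tol.

    Default pool-size rule when no k is imposed: walk k upward and stop at
    the stability plateau; falls back to k_max when no plateau appears.
    """
    n = len(result.table)
    k_max = k_max if k_max is not None else min(25, n - 1)
    prev = None
    for k in range(k_min, k_max + 1):
        cur = kuncheva_index(result.partition_selections(k), n)
        if prev is not None and abs(cur - prev) < tol:
            return k - 1
        prev = cur
    return k_max
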