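"""Between-site profile comparison and confounded-feature exclusion.

Plasma miRNA profiles differ between recruitment populations; any miRNA that
discriminates both disease status and recruitment site is a confounder for a
cross-population diagnostic signature.  Three screens run on the combined
two-site matrix: PCA of the normalized profiles (site separation shows up on
the leading components), random-forest feature selection with *site* as the
class label, and a per-feature Kruskal-Wallis rank test across sites.  The
default confounder call is the triple intersection of the top cancer-
discriminating set with both site-discriminating sets; a stricter
cancer ∩ (RF-site ∪ KW-site) variant is available.  Flagged miRNAs are
excluded column-wise; delta-Cq values are not recomputed (exclusion does not
touch the normalizer set unless a flagged miRNA happened to be a normalizer,
which per-dataset re-normalization would handle upstream).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .featsel import FeatureSelectionResult, rf_importance, select_features
from .io_model import ForestConfig, NormalizedMatrix, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_TOP_M = 25


@dataclass
class PcaResult:
    projections: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    dropped_features: tuple[str, ...]


def pca_sites(
    nm_combined: NormalizedMatrix, n_components: int = 10
) -> PcaResult:
    """PCA of mean-centered delta-Cq profiles (unscaled: all features share
    Cq units).  Features with any missingness are dropped with a warning."""
    complete = [m for m in nm_combined.mirna_ids if not nm_combined.frame[m].isna().any()]
    dropped = tuple(m for m in nm_combined.mirna_ids if m not in set(complete))
    if dropped:
        logger.warning("PCA: dropping %d features with missing values", len(dropped))
    if len(complete) < 2:
        raise ValidationError("PCA needs >= 2 complete features")
    if len(nm_combined.sample_ids) < 3:
        raise ValidationError("PCA needs >= 3 samples")
    X = nm_combined.frame[complete].to_numpy()
    X = X - X.mean(axis=0)
    k = min(n_components, min(X.shape) - 1)
    pca = PCA(n_components=k, svd_solver="full")
    proj = pca.fit_transform(X)
    return PcaResult(
        projections=pd.DataFrame(
            proj, index=nm_combined.sample_ids, columns=[f"PC{i+1}" for i in range(k)]
        ),
        explained_variance_ratio=pca.explained_variance_ratio_,
        dropped_features=dropped,
    )


def rf_site_discrimination(
    nm_combined: NormalizedMatrix,
    site_labels,
    cfg: ForestConfig,
    m: int = DEFAULT_TOP_M,
) -> tuple[list[str], FeatureSelectionResult]:
    """Top-m miRNAs separating the two recruitment sites, by the same
    forest-importance machinery used for disease selection (site as class)."""
    sites = pd.Series(site_labels) if not isinstance(site_labels, pd.Series) else site_labels
    uniq = sorted(set(sites[s] for s in nm_combined.sample_ids))
    if len(uniq) != 2:
        raise ValidationError(f"expected exactly 2 sites, got {uniq}")
    # map the two site labels onto the binary class machinery
    mapped = {s: ("cancer" if sites[s] == uniq[1] else "healthy") for s in nm_combined.sample_ids}
    result = rf_importance(nm_combined, mapped, cfg)
    return select_features(result.table, min(m, len(result.table))), result


def kruskal_wallis_screen(
    nm_combined: NormalizedMatrix, site_labels, m: int = DEFAULT_TOP_M
) -> tuple[list[str], pd.DataFrame]:
    """Per-feature Kruskal-Wallis H across site groups (rank-based,
    tie-corrected).  Returns the top-m features by ascending p (ties by
    descending H then name) and the full statistics table.  Constant
    features get H = 0, p = 1 with a warning."""
    sites = pd.Series(site_labels) if not isinstance(site_labels, pd.Series) else site_labels
    groups = sites[nm_combined.sample_ids]
    rows = []
    for mirna in nm_combined.mirna_ids:
        col = nm_combined.frame[mirna]
        samples = [
            col[groups == g].dropna().to_numpy() for g in sorted(groups.unique())
        ]
        if any(len(s) < 2 for s in samples):
            raise ValidationError(
                f"feature {mirna!r}: fewer than 2 present values in a site group"
            )
        pooled = np.concatenate(samples)
        if np.ptp(pooled) == 0:
            logger.warning("feature %s constant across sites; H=0, p=1", mirna)
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*samples)
        rows.append({"mirna": mirna, "H": float(h), "p": float(p)})
    table = pd.DataFrame(rows).set_index("mirna")
    order = sorted(table.index, key=lambda name: (table.loc[name, "p"], -table.loc[name, "H"], name))
    return order[: min(m, len(order))], table


def confounded_features(
    cancer_set, rf_site_set, kw_site_set, rule: str = "intersection"
) -> set[str]:
    """Disease-discriminating miRNAs that also discriminate recruitment site.

    ``intersection`` (default): cancer ∩ RF-site ∩ KW-site — a miRNA is
    flagged only when both site screens agree.  ``union``: cancer ∩
    (RF-site ∪ KW-site) — stricter exclusion, either screen suffices.
    """
    cancer_set, rf_site_set, kw_site_set = set(cancer_set), set(rf_site_set), set(kw_site_set)
    if rule == "intersection":
        return cancer_set & rf_site_set & kw_site_set
    if rule == "union":
        return cancer_set & (rf_site_set | kw_site_set)
    raise ValidationError(f"unknown confounder rule {rule!r}")


def venn_table(cancer_set, rf_site_set, kw_site_set) -> pd.DataFrame:
    """Membership table behind the three-set overlap diagram."""
    universe = sorted(set(cancer_set) | set(rf_site_set) | set(kw_site_set))
    return pd.DataFrame(
        {
            "cancer": [m in set(cancer_set) for m in universe],
            "rf_site": [m in set(rf_site_set) for m in universe],
            "kw_site": [m in set(kw_site_set) for m in universe],
        },
        index=pd.Index(universe, name="mirna"),
    )


def exclude_features(nm: NormalizedMatrix, flagged) -> NormalizedMatrix:
    """Drop flagged columns; every remaining delta-Cq value is untouched
    (normalization is not recomputed).  Flagged names absent from the matrix
    are ignored with a warning."""
    flagged = set(flagged)
    extra = flagged - set(nm.mirna_ids)
    if extra:
        logger.warning("flagged miRNAs absent from matrix, ignored: %s", sorted(extra))
    keep = [m for m in nm.mirna_ids if m not in flagged]
    if len(keep) < 2:
        raise ValidationError("exclusion would leave fewer than 2 features")
    return NormalizedMatrix(
        nm.frame[keep].copy(), nm.normalizer_set, nm.source_dataset_id
    )
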