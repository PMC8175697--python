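"""QC filtering, panel harmonization, delta-Cq normalization, cohort matching.

Normalization follows the global-reference delta-Cq scheme: each sample's Cq
values are expressed relative to the mean Cq of that sample over the n_norm
(default 50) most expressed miRNAs of the *same dataset*.  "Most expressed"
means lowest mean present Cq across the dataset; the reference set is
recomputed per dataset, so design and validation cohorts are normalized
independently — no statistic of the validation set leaks into the design set.
Missing Cq values are excluded from both the ranking mean and each sample's
normalizer mean; nothing is imputed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_model import (
    CqMatrix,
    NormalizedMatrix,
    Panel,
    SampleRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)

HEMOLYSIS_THRESHOLD = 5.0  # ABS414 above this excludes the sample
N_NORMALIZERS = 50


def filter_hemolysis(
    records: list[SampleRecord], threshold: float = HEMOLYSIS_THRESHOLD
) -> list[SampleRecord]:
    """Drop hemolysed samples: ABS414 strictly greater than ``threshold``.

    Records without an ABS414 measurement are retained with a warning (they
    cannot be judged).  The boundary value is retained — exclusion is strict.
    """
    if threshold < 0:
        raise ValidationError(f"hemolysis threshold must be >= 0, got {threshold}")
    kept: list[SampleRecord] = []
    n_missing = 0
    for r in records:
        if r.abs414 is None:
            n_missing += 1
            kept.append(r)
        elif r.abs414 <= threshold:
            kept.append(r)
    if n_missing:
        logger.warning(
            "%d records lack ABS414; passed through hemolysis filter unchecked",
            n_missing,
        )
    return kept


def harmonize_panels(a: Panel, b: Panel) -> Panel:
    """Intersect two panels, preserving ``a``'s ordering."""
    in_b = set(b.mirna_ids)
    common = tuple(m for m in a.mirna_ids if m in in_b)
    if not common:
        raise ValidationError(
            f"panels {a.name!r} and {b.name!r} share no miRNAs"
        )
    return Panel(f"{a.name}&{b.name}", common)


def select_top_expressed(m: CqMatrix, n_norm: int = N_NORMALIZERS) -> tuple[str, ...]:
    """The ``n_norm`` miRNAs with lowest mean present Cq (most abundant).

    Ties at the cut are broken lexicographically by miRNA name.  miRNAs never
    detected in any sample carry no expression information and are not
    candidates.
    """
    means = m.frame.mean(axis=0, skipna=True)
    means = means.dropna()
    if len(means) < n_norm:
        raise ValidationError(
            f"only {len(means)} miRNAs with >=1 present Cq; cannot select {n_norm}"
        )
    order = sorted(means.index, key=lambda name: (means[name], name))
    return tuple(order[:n_norm])


def normalize_delta_cq(
    m: CqMatrix,
    normalizer_set: tuple[str, ...] | None = None,
    n_norm: int = N_NORMALIZERS,
    dataset_id: str = "",
) -> NormalizedMatrix:
    """Express each Cq relative to the sample's mean over the normalizer set.

    delta_cq(s, m) = Cq(s, m) - mean_{r in normalizer_set, present} Cq(s, r).
    When ``normalizer_set`` is None it is selected from this same matrix via
    :func:`select_top_expressed` (per-dataset recomputation).
    """
    if normalizer_set is None:
        normalizer_set = select_top_expressed(m, n_norm)
    normalizer_set = tuple(normalizer_set)
    missing = set(normalizer_set) - set(m.mirna_ids)
    if missing:
        raise ValidationError(f"normalizer miRNAs absent from matrix: {sorted(missing)}")
    ref = m.frame.loc[:, list(normalizer_set)]
    ref_mean = ref.mean(axis=1, skipna=True)
    dead = ref_mean.index[ref_mean.isna()]
    if len(dead):
        raise ValidationError(
            f"sample(s) with no detected normalizer miRNA: {list(dead)}"
        )
    delta = m.frame.sub(ref_mean, axis=0)
    return NormalizedMatrix(delta, normalizer_set, dataset_id)


def match_cohorts(
    site_a_records: list[SampleRecord], site_b_records: list[SampleRecord]
) -> tuple[list[tuple[SampleRecord, SampleRecord]], list[SampleRecord], list[SampleRecord]]:
    """Pair subjects across sites within (class, subtype) strata by age.

    Greedy: within each stratum, repeatedly pair the remaining cross-site
    couple with the smallest absolute age difference (ties broken by sample
    id) until one side is exhausted.  Returns (pairs, unmatched site A,
    unmatched site B); a stratum populated on one side only is left unmatched
    with a warning.  By construction the matched output has equal class and
    subtype counts on both sites.
    """
    def strata(records):
        out: dict[tuple[str, str], list[SampleRecord]] = {}
        for r in records:
            out.setdefault((r.klass, r.subtype), []).append(r)
        return out

    sa, sb = strata(site_a_records), strata(site_b_records)
    pairs: list[tuple[SampleRecord, SampleRecord]] = []
    matched_a: set[str] = set()
    matched_b: set[str] = set()
    for stratum in sorted(set(sa) | set(sb)):
        a_pool = sorted(sa.get(stratum, []), key=lambda r: r.sample_id)
        b_pool = sorted(sb.get(stratum, []), key=lambda r: r.sample_id)
        if not a_pool or not b_pool:
            if a_pool or b_pool:
                logger.warning(
                    "stratum %s present on one site only (%d vs %d); unmatched",
                    stratum, len(a_pool), len(b_pool),
                )
            continue
        while a_pool and b_pool:
            best = min(
                ((a, b) for a in a_pool for b in b_pool),
                key=lambda ab: (abs(ab[0].age - ab[1].age), ab[0].sample_id, ab[1].sample_id),
            )
            pairs.append(best)
            matched_a.add(best[0].sample_id)
            matched_b.add(best[1].sample_id)
            a_pool.remove(best[0])
            b_pool.remove(best[1])
    leftovers_a = [r for r in site_a_records if r.sample_id not in matched_a]
    leftovers_b = [r for r in site_b_records if r.sample_id not in matched_b]
    return pairs, leftovers_a, leftovers_b
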