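"""Canned study-condition experiments on synthetic two-site cohorts.

These drivers wire the pipeline stages into the three headline checks the
synthetic ground truth supports:

- planted-feature recovery (does combined-rank selection find the disease
  miRNAs at a realistic effect size?),
- the same-site vs cross-site validation gap in the presence of
  disease-by-site confounded miRNAs, and whether excluding the flagged
  confounders shrinks it,
- null calibration (with no injected effects, validation AUC centers on 0.5).

Problem sizes are reduced relative to the full study design (fewer trees,
partitions and miRNAs) so a complete experiment runs on a single desk CPU
in minutes; the generative effect sizes (-2 Cq disease shift, +/-2 Cq site
shift, 0.5 Cq measurement noise, 1 Cq sample offsets) are kept at the
realistic scale the default generator uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import featsel, popcompare, preprocess, sigsearch, valroc
from .io_model import ForestConfig
from .simdata import Cohort, SimConfig, generate_matched_rest

DISEASE_DELTA = -2.0
SITE_DELTA = 2.0
SIGMA_NOISE = 0.5
SIGMA_SAMPLE = 1.0


def _effects(n_disease: int = 5, n_confounded: int = 2, n_site_only: int = 8):
    """Planted effect sets on the synthetic namespace: ``n_confounded`` of the
    disease miRNAs also carry a site shift (the confounding structure)."""
    names = [f"hsa-miR-{7100 + i}-3p" for i in range(40)]
    disease = {m: DISEASE_DELTA for m in names[:n_disease]}
    site = {m: SITE_DELTA for m in names[n_disease - n_confounded: n_disease]}
    site.update(
        {
            names[n_disease + i]: SITE_DELTA if i % 2 == 0 else -SITE_DELTA
            for i in range(n_site_only)
        }
    )
    return disease, site


def _labels(cohort: Cohort) -> dict[str, str]:
    return {r.sample_id: r.klass for r in cohort.records}


def _pool_cohorts(cohorts: list[Cohort], name: str) -> Cohort:
    from .pipeline import _pool_cohorts as pool

    return pool(cohorts, name)


def _design_and_validate(nm_design, design_labels, validations, cfg, pool_k):
    """Select a pool, enumerate, search, and validate the full candidate list.

    ``validations``: mapping name -> (NormalizedMatrix, labels).  Returns the
    pool and {name: [validation AUCs]} over all 2^k - 1 signatures.
    """
    fs = featsel.rf_importance(nm_design, design_labels, cfg)
    pool = featsel.select_features(fs.table, pool_k)
    ensembles = sigsearch.search_signatures(
        sigsearch.enumerate_signatures(pool), nm_design, design_labels, cfg
    )
    shortlist = sigsearch.filter_signatures(ensembles, 0.0)
    out: dict[str, list[float]] = {}
    for name, (nm_val, labels) in validations.items():
        aucs = []
        for ens in shortlist:
            perf = valroc.validate_signature(ens, nm_val, labels, cohort_id=name)
            if not isinstance(perf, valroc.DiscardEvent):
                aucs.append(perf.validation_auc)
        out[name] = aucs
    return pool, shortlist, out


@dataclass
class ConfoundingResult:
    pool: list[str]
    flagged: set[str]
    truth_confounded: set[str]
    n_signatures: int
    same_site_auc: float
    cross_site_auc: float
    gap: float
    same_site_auc_excluded: float
    cross_site_auc_excluded: float
    gap_after_exclusion: float


def confounding_experiment(
    seed: int = 0,
    n_per_group: int = 50,
    n_mirnas: int = 60,
    matched_n: int = 30,
    pool_k: int = 5,
    cfg: ForestConfig | None = None,
    n_norm: int = 20,
) -> ConfoundingResult:
    """Design at one site, validate same-site and cross-site, then repeat
    after excluding the miRNAs flagged as site-confounded.

    The design cohort is MATCHED-BE; same-site validation is REST-BE and
    cross-site validation the pooled RW site.  Two of the five planted
    disease miRNAs also carry a +2 Cq site shift, so signatures using them
    should degrade cross-site; the three screens (disease-RF, site-RF,
    Kruskal-Wallis) flag the overlap and exclusion should shrink the gap.
    """
    cfg = cfg or ForestConfig(
        ntree=100, n_design_repeats=10, n_fs_partitions=15, seed=seed
    )
    disease, site = _effects()
    sim = SimConfig(
        n_per_group_per_site=n_per_group,
        n_mirnas=n_mirnas,
        disease_mirnas=disease,
        site_mirnas=site,
        sigma_noise=SIGMA_NOISE,
        sigma_sample=SIGMA_SAMPLE,
        lod_cq=50.0,
        seed=seed,
    )
    cohorts, truth = generate_matched_rest(sim, matched_n=matched_n)

    design = cohorts["MATCHED-BE"]
    same_site = cohorts["REST-BE"]
    cross_site = _pool_cohorts([cohorts["MATCHED-RW"], cohorts["REST-RW"]], "ALL-RW")

    def normalize(c: Cohort):
        return preprocess.normalize_delta_cq(c.cq, n_norm=n_norm, dataset_id=c.name)

    nm_design = normalize(design)
    validations = {
        "same": (normalize(same_site), _labels(same_site)),
        "cross": (normalize(cross_site), _labels(cross_site)),
    }
    pool, shortlist, aucs = _design_and_validate(
        nm_design, _labels(design), validations, cfg, pool_k
    )
    same_auc = float(np.mean(aucs["same"]))
    cross_auc = float(np.mean(aucs["cross"]))

    # confounder screens on the pooled two-site data
    combined = _pool_cohorts(list(cohorts.values()), "ALL")
    nm_all = preprocess.normalize_delta_cq(combined.cq, n_norm=n_norm, dataset_id="ALL")
    site_of = {r.sample_id: r.site for r in combined.records}
    cancer_fs = featsel.rf_importance(nm_all, _labels(combined), cfg)
    cancer_top = featsel.select_features(cancer_fs.table, pool_k)
    rf_top, _ = popcompare.rf_site_discrimination(nm_all, site_of, cfg, m=2 * pool_k)
    kw_top, _ = popcompare.kruskal_wallis_screen(nm_all, site_of, m=2 * pool_k)
    flagged = popcompare.confounded_features(cancer_top, rf_top, kw_top)

    nm_design_x = popcompare.exclude_features(nm_design, flagged)
    validations_x = {
        name: (popcompare.exclude_features(nm, flagged), labels)
        for name, (nm, labels) in validations.items()
    }
    _, _, aucs_x = _design_and_validate(
        nm_design_x, _labels(design), validations_x, cfg, pool_k
    )
    same_x = float(np.mean(aucs_x["same"]))
    cross_x = float(np.mean(aucs_x["cross"]))

    return ConfoundingResult(
        pool=pool,
        flagged=flagged,
        truth_confounded=truth.confounded_set,
        n_signatures=len(shortlist),
        same_site_auc=same_auc,
        cross_site_auc=cross_auc,
        gap=same_auc - cross_auc,
        same_site_auc_excluded=same_x,
        cross_site_auc_excluded=cross_x,
        gap_after_exclusion=same_x - cross_x,
    )


@dataclass
class NullCalibrationResult:
    n_signatures: int
    mean_validation_auc: float
    validation_aucs: list[float]


def null_calibration_experiment(
    seed: int = 0,
    n_per_group: int = 80,
    n_mirnas: int = 40,
    matched_n: int = 50,
    pool_k: int = 5,
    cfg: ForestConfig | None = None,
    n_norm: int = 15,
) -> NullCalibrationResult:
    """With all effects zero, the shortlist's validation AUCs center on 0.5.

    Feature selection still overfits the design set (it picks the apparently
    best noise features), but the independently normalized validation pool
    carries no signal, so validation AUC is unbiased around chance.
    """
    cfg = cfg or ForestConfig(
        ntree=100, n_design_repeats=10, n_fs_partitions=15, seed=seed
    )
    sim = SimConfig(
        n_per_group_per_site=n_per_group,
        n_mirnas=n_mirnas,
        disease_mirnas={},
        site_mirnas={},
        sigma_noise=SIGMA_NOISE,
        sigma_sample=SIGMA_SAMPLE,
        lod_cq=50.0,
        seed=seed,
    )
    cohorts, _ = generate_matched_rest(sim, matched_n=matched_n)
    design = cohorts["MATCHED-BE"]
    validation = _pool_cohorts([cohorts["REST-BE"], cohorts["REST-RW"]], "REST-ALL")
    nm_design = preprocess.normalize_delta_cq(design.cq, n_norm=n_norm, dataset_id="d")
    nm_val = preprocess.normalize_delta_cq(validation.cq, n_norm=n_norm, dataset_id="v")
    _, shortlist, aucs = _design_and_validate(
        nm_design, _labels(design), {"val": (nm_val, _labels(validation))}, cfg, pool_k
    )
    return NullCalibrationResult(
        n_signatures=len(shortlist),
        mean_validation_auc=float(np.mean(aucs["val"])),
        validation_aucs=aucs["val"],
    )


@dataclass
class RecoveryResult:
    n_runs: int
    n_successes: int
    per_run_recovered: list[int]

    @property
    def success_rate(self) -> float:
        return self.n_successes / self.n_runs


def recovery_experiment(
    seed: int = 0,
    n_runs: int = 10,
    n_disease: int = 5,
    n_mirnas: int = 50,
    n_per_group: int = 50,
    cfg: ForestConfig | None = None,
    min_recovered: int = 4,
) -> RecoveryResult:
    """Planted-feature recovery: five -2 Cq disease miRNAs among noise,
    selection size k = 5; a run succeeds when >= ``min_recovered`` planted
    miRNAs are recovered."""
    cfg = cfg or ForestConfig(ntree=100, n_design_repeats=10, n_fs_partitions=25, seed=seed)
    recovered_counts = []
    for run in range(n_runs):
        run_seed = seed + 1000 * run
        disease = {f"hsa-miR-{7100 + i}-3p": DISEASE_DELTA for i in range(n_disease)}
        sim = SimConfig(
            n_per_group_per_site={"BE": {"cancer": n_per_group, "healthy": n_per_group},
                                  "RW": {"cancer": 2, "healthy": 2}},
            n_mirnas=n_mirnas,
            disease_mirnas=disease,
            site_mirnas={},
            sigma_noise=SIGMA_NOISE,
            sigma_sample=SIGMA_SAMPLE,
            lod_cq=50.0,
            seed=run_seed,
        )
        from .simdata import generate_study

        study = generate_study(sim)
        nm = preprocess.normalize_delta_cq(study.cq["BE"], n_norm=15, dataset_id="d")
        labels = {r.sample_id: r.klass for r in study.records["BE"]}
        run_cfg = ForestConfig(
            ntree=cfg.ntree,
            n_design_repeats=cfg.n_design_repeats,
            n_fs_partitions=cfg.n_fs_partitions,
            seed=run_seed,
        )
        fs = featsel.rf_importance(nm, labels, run_cfg)
        selected = set(featsel.select_features(fs.table, n_disease))
        recovered_counts.append(len(selected & set(disease)))
    successes = sum(c >= min_recovered for c in recovered_counts)
    return RecoveryResult(
        n_runs=n_runs, n_successes=successes, per_run_recovered=recovered_counts
    )
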