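"""Configured end-to-end experiment runs.

An experiment mirrors one of the study designs:

- ``apply_existing_signatures`` — fit forests for a fixed list of published
  signatures on the design cohort and validate them on independent cohorts.
- ``mixed_design``      — design on the pooled two-site matched cohorts
  (optionally after confounder exclusion), validate on the REST cohorts.
- ``single_site_design`` — design and validate within one recruitment site.

Every run consumes synthetic cohorts from :mod:`mirsig.simdata` (or cohorts
loaded from disk), applies hemolysis QC, harmonizes panels across the
cohorts involved, normalizes every cohort *independently* (per-dataset
top-expressed normalizer sets), and writes all result tables plus a manifest
(config + seeds + split descriptors) sufficient for bit-identical replay.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import featsel, popcompare, preprocess, sigsearch, valroc
from .io_model import (
    CqMatrix,
    ForestConfig,
    NormalizedMatrix,
    Panel,
    Signature,
    ValidationError,
    write_config,
    write_report,
)
from .simdata import Cohort, SimConfig, generate_matched_rest

logger = logging.getLogger(__name__)

SCENARIOS = ("apply_existing_signatures", "mixed_design", "single_site_design")


@dataclass
class ExperimentConfig:
    scenario: str = "mixed_design"
    design_cohorts: tuple[str, ...] = ("MATCHED-BE", "MATCHED-RW")
    validation_cohorts: tuple[str, ...] = ("REST-BE", "REST-RW")
    forest: ForestConfig = field(default_factory=ForestConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    matched_n: int = 55
    hemolysis_threshold: float = preprocess.HEMOLYSIS_THRESHOLD
    n_norm: int = preprocess.N_NORMALIZERS
    top_k: int | None = None  # feature-pool size; None = stability plateau
    top_m: int = popcompare.DEFAULT_TOP_M
    auc_min: float = 0.82
    compare_populations: bool = False
    confounder_rule: str = "intersection"
    signatures: tuple[Signature, ...] = ()  # for apply_existing_signatures
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValidationError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "apply_existing_signatures" and not self.signatures:
            raise ValidationError("apply_existing_signatures needs a signature list")
        if not self.validation_cohorts:
            raise ValidationError("at least one validation cohort is required")
        overlap = set(self.design_cohorts) & set(self.validation_cohorts)
        if overlap:
            raise ValidationError(
                f"design and validation cohorts overlap: {sorted(overlap)} "
                "(independence of the validation is the point)"
            )


@dataclass
class ExperimentResult:
    cohorts: dict[str, Cohort]
    design_nm: NormalizedMatrix
    validation_nms: dict[str, NormalizedMatrix]
    pool: list[str]
    ensembles: list
    shortlist: list
    performances: dict[str, list[valroc.SignaturePerformance]]
    discards: dict[str, list[valroc.DiscardEvent]]
    flagged: set[str]
    truth: object | None = None


def _qc_cohort(cohort: Cohort, threshold: float) -> Cohort:
    kept = preprocess.filter_hemolysis(cohort.records, threshold)
    ids = [r.sample_id for r in kept]
    return Cohort(cohort.name, cohort.cq.subset_samples(ids), kept)


def _pool_cohorts(cohorts: list[Cohort], name: str) -> Cohort:
    """Concatenate cohorts on their common (harmonized) panel."""
    panel = Panel(cohorts[0].name, tuple(cohorts[0].cq.mirna_ids))
    for c in cohorts[1:]:
        panel = preprocess.harmonize_panels(panel, Panel(c.name, tuple(c.cq.mirna_ids)))
    frames = [c.cq.frame.loc[:, list(panel.mirna_ids)] for c in cohorts]
    ids = [r.sample_id for c in cohorts for r in c.records]
    if len(set(ids)) != len(ids):
        raise ValidationError("cohorts share sample ids; cannot pool")
    merged = CqMatrix(pd.concat(frames, axis=0))
    return Cohort(name, merged, [r for c in cohorts for r in c.records])


def _normalize(cohort: Cohort, n_norm: int) -> NormalizedMatrix:
    return preprocess.normalize_delta_cq(
        cohort.cq, None, n_norm=n_norm, dataset_id=cohort.name
    )


def run_experiment(
    config: ExperimentConfig,
    outdir: str | Path | None = None,
    cohorts: dict[str, Cohort] | None = None,
) -> ExperimentResult:
    """Execute one configured experiment; optionally write a run directory.

    ``cohorts`` may supply pre-built cohorts (e.g. loaded from disk);
    otherwise they are simulated from ``config.sim``.
    """
    t0 = time.time()
    truth = None
    if cohorts is None:
        cohorts, truth = generate_matched_rest(config.sim, config.matched_n)

    needed = set(config.design_cohorts) | set(config.validation_cohorts)
    missing = needed - set(cohorts)
    if missing:
        raise ValidationError(f"unknown cohort name(s): {sorted(missing)}")

    qc = {name: _qc_cohort(cohorts[name], config.hemolysis_threshold) for name in cohorts}

    design = _pool_cohorts([qc[n] for n in config.design_cohorts], "DESIGN")
    design_ids = {r.sample_id for r in design.records}
    for name in config.validation_cohorts:
        overlap = design_ids & {r.sample_id for r in qc[name].records}
        if overlap:
            raise ValidationError(
                f"validation cohort {name} shares {len(overlap)} sample(s) with the design set"
            )

    nm_design = _normalize(design, config.n_norm)
    validation_nms = {
        name: _normalize(qc[name], config.n_norm) for name in config.validation_cohorts
    }

    flagged: set[str] = set()
    venn = None
    if config.compare_populations:
        combined = _pool_cohorts(list(qc.values()), "ALL")
        nm_all = _normalize(combined, config.n_norm)
        site_of = {r.sample_id: r.site for r in combined.records}
        klass_of = {r.sample_id: r.klass for r in combined.records}
        cancer_res = featsel.rf_importance(nm_all, klass_of, config.forest)
        cancer_top = featsel.select_features(
            cancer_res.table, min(config.top_m, len(cancer_res.table))
        )
        rf_top, _ = popcompare.rf_site_discrimination(
            nm_all, pd.Series(site_of), config.forest, m=config.top_m
        )
        kw_top, _ = popcompare.kruskal_wallis_screen(nm_all, pd.Series(site_of), m=config.top_m)
        flagged = popcompare.confounded_features(
            cancer_top, rf_top, kw_top, rule=config.confounder_rule
        )
        venn = popcompare.venn_table(cancer_top, rf_top, kw_top)
        if flagged:
            nm_design = popcompare.exclude_features(nm_design, flagged)
            validation_nms = {
                n: popcompare.exclude_features(v, flagged) for n, v in validation_nms.items()
            }

    design_labels = {r.sample_id: r.klass for r in design.records}
    fs_result = None
    if config.scenario == "apply_existing_signatures":
        pool: list[str] = []
        candidates = list(config.signatures)
    else:
        fs_result = featsel.rf_importance(nm_design, design_labels, config.forest)
        k = config.top_k or featsel.stability_plateau_k(fs_result)
        pool = featsel.select_features(fs_result.table, k)
        candidates = sigsearch.enumerate_signatures(pool)

    ensembles = sigsearch.search_signatures(candidates, nm_design, design_labels, config.forest)
    shortlist = sigsearch.filter_signatures(ensembles, config.auc_min)

    performances: dict[str, list[valroc.SignaturePerformance]] = {}
    discards: dict[str, list[valroc.DiscardEvent]] = {}
    for name, nm_val in validation_nms.items():
        labels = {r.sample_id: r.klass for r in qc[name].records}
        perfs, drops = [], []
        for ens in shortlist:
            out = valroc.validate_signature(ens, nm_val, labels, cohort_id=name)
            (drops if isinstance(out, valroc.DiscardEvent) else perfs).append(out)
        performances[name] = perfs
        discards[name] = drops

    result = ExperimentResult(
        cohorts=cohorts,
        design_nm=nm_design,
        validation_nms=validation_nms,
        pool=pool,
        ensembles=ensembles,
        shortlist=shortlist,
        performances=performances,
        discards=discards,
        flagged=flagged,
        truth=truth,
    )
    if outdir is not None:
        _write_run(config, result, fs_result, venn, Path(outdir), time.time() - t0)
    return result


def _write_run(config, result, fs_result, venn, outdir: Path, elapsed: float) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "scenario": config.scenario,
        "design_cohorts": list(config.design_cohorts),
        "validation_cohorts": list(config.validation_cohorts),
        "seed": config.seed,
        "forest": {
            "ntree": config.forest.ntree,
            "seed": config.forest.seed,
            "n_design_repeats": config.forest.n_design_repeats,
            "train_fraction": config.forest.train_fraction,
            "n_fs_partitions": config.forest.n_fs_partitions,
        },
        "thresholds": {
            "hemolysis": config.hemolysis_threshold,
            "n_norm": config.n_norm,
            "auc_min": config.auc_min,
            "top_k": config.top_k,
            "top_m": config.top_m,
        },
        "sim_seed": config.sim.seed,
        "matched_n": config.matched_n,
        "flagged": sorted(result.flagged),
        "elapsed_seconds": round(elapsed, 3),
    }
    write_config(manifest, outdir / "manifest.yaml")
    # normalizer audit: the per-dataset reference sets
    audit = {
        "DESIGN": list(result.design_nm.normalizer_set),
        **{n: list(v.normalizer_set) for n, v in result.validation_nms.items()},
    }
    write_config(audit, outdir / "normalizer_audit.yaml")
    if fs_result is not None:
        fs_result.table.to_csv(outdir / "importance.csv")
    if venn is not None:
        venn.to_csv(outdir / "venn.csv")
    sigsearch.shortlist_table(result.shortlist).to_csv(outdir / "shortlist.csv", index=False)
    for name, perfs in result.performances.items():
        write_report(perfs, outdir / f"performance_{name}.csv")
        if result.discards[name]:
            pd.DataFrame(
                [
                    {"signature": d.signature_name, "missing": "+".join(sorted(d.missing_mirnas))}
                    for d in result.discards[name]
                ]
            ).to_csv(outdir / f"discards_{name}.csv", index=False)
    splits = []
    for ens in result.shortlist[:1]:  # shared splits: one descriptor suffices
        for i, sp in enumerate(ens.splits):
            splits.append(
                {"repeat": i, "train": "+".join(sp.train_ids), "test": "+".join(sp.test_ids)}
            )
    if splits:
        pd.DataFrame(splits).to_csv(outdir / "design_splits.csv", index=False)
    logger.info("run written to %s (%.1f s)", outdir, elapsed)


def simulate(config: SimConfig, outdir: str | Path, matched_n: int = 55) -> dict[str, Cohort]:
    """Generate the four MATCHED/REST cohorts and write them to disk."""
    from .io_model import write_cq_table, write_metadata

    cohorts, truth = generate_matched_rest(config, matched_n)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, cohort in cohorts.items():
        write_cq_table(cohort.cq, outdir / f"cq_{name}.csv")
        write_metadata(cohort.records, outdir / f"meta_{name}.csv")
    truth.write(outdir / "truth.yaml")
    write_config({"seed": config.seed, "matched_n": matched_n}, outdir / "sim_manifest.yaml")
    return cohorts
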