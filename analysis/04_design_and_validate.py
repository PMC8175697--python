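#!/usr/bin/env python
"""Design signatures on the matched cohorts and validate on the REST cohorts.

Feature selection (combined MDA/MDG rank with stability indices) on the
pooled matched design set after excluding the flagged confounders, exhaustive
enumeration of the selected pool, repeated-split design AUC for every
candidate, and validation of the shortlist on the independently normalized
REST cohorts.  Writes the importance table, stability report, shortlist and
Table-3-style performance tables under results/signatures/.
(Run 01-03 first.)
"""

from pathlib import Path

import pandas as pd
import yaml

from mirsig import featsel, popcompare, sigsearch, valroc
from mirsig.io_model import ForestConfig, NormalizedMatrix, read_metadata, write_report

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 1
POOL_K = 5
AUC_MIN = 0.82


def _load(name: str) -> tuple[NormalizedMatrix, dict[str, str]]:
    df = pd.read_csv(ROOT / "normalized" / f"delta_cq_{name}.csv", index_col=0)
    labels = {
        r.sample_id: r.klass
        for r in read_metadata(ROOT / "cohorts" / f"meta_{name}.csv")
    }
    return NormalizedMatrix(df, tuple(df.columns[:1]), name), labels


def main() -> None:
    out = ROOT / "signatures"
    out.mkdir(parents=True, exist_ok=True)
    flagged = set(
        pd.read_csv(ROOT / "popcompare" / "flagged.csv")["mirna"].tolist()
        if (ROOT / "popcompare" / "flagged.csv").stat().st_size > 10
        else []
    )
    nm_be, labels_be = _load("MATCHED-BE")
    nm_rw, labels_rw = _load("MATCHED-RW")
    design = NormalizedMatrix(
        pd.concat([nm_be.frame, nm_rw.frame]), nm_be.normalizer_set, "DESIGN"
    )
    if flagged:
        design = popcompare.exclude_features(design, flagged)
        print(f"excluded {len(flagged)} confounded miRNAs from the design set")
    labels = {**labels_be, **labels_rw}

    cfg = ForestConfig.desk(seed=SEED, n_fs_partitions=15)
    fs = featsel.rf_importance(design, labels, cfg)
    fs.table.to_csv(out / "importance.csv")
    pool = featsel.select_features(fs.table, POOL_K)
    rep = featsel.stability(
        fs.partition_selections(POOL_K), len(fs.table), fs.partition_orderings()
    )
    (out / "stability.yaml").write_text(yaml.safe_dump({
        "kuncheva_index": rep.kuncheva_index,
        "spearman_index": rep.spearman_index,
        "n_partitions": rep.n_partitions,
        "selection_size": rep.selection_size,
    }))
    print(f"pool (top {POOL_K} by combined rank): {pool}")
    print(f"stability: Kuncheva {rep.kuncheva_index:.2f}, "
          f"Spearman {rep.spearman_index:.2f} over {rep.n_partitions} partitions")

    candidates = sigsearch.enumerate_signatures(pool)
    ensembles = sigsearch.search_signatures(candidates, design, labels, cfg)
    shortlist = sigsearch.filter_signatures(ensembles, AUC_MIN)
    sigsearch.shortlist_table(shortlist).to_csv(out / "shortlist.csv", index=False)
    print(f"{len(candidates)} candidate signatures; "
          f"{len(shortlist)} with design AUC >= {AUC_MIN}")

    for name in ("REST-BE", "REST-RW"):
        nm_val, labels_val = _load(name)
        if flagged:
            nm_val = popcompare.exclude_features(nm_val, flagged)
        perfs, discards = [], []
        for ens in shortlist:
            res = valroc.validate_signature(ens, nm_val, labels_val, cohort_id=name)
            (discards if isinstance(res, valroc.DiscardEvent) else perfs).append(res)
        write_report(perfs, out / f"performance_{name}.csv")
        if perfs:
            top = max(perfs, key=lambda p: p.validation_auc)
            print(f"{name}: best validation AUC {top.validation_auc:.3f} "
                  f"[{top.ci_low:.3f}, {top.ci_high:.3f}], cutoff {top.cutoff:.3f}, "
                  f"sens {top.sensitivity:.2f} / spec {top.specificity:.2f} "
                  f"({top.n_mirnas} miRNAs); {len(discards)} discarded")


if __name__ == "__main__":
    main()
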