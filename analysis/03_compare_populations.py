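#!/usr/bin/env python
"""Compare the two recruitment sites on the pooled normalized data.

PCA of the combined profiles, forest-based site discrimination, the
Kruskal-Wallis site screen, and the three-set overlap with the top
cancer-discriminating miRNAs.  The overlap members are the candidate
disease-by-site confounders.  Writes tables under results/popcompare/.
(Run 01 and 02 first.)
"""

from pathlib import Path

import pandas as pd
from sklearn.metrics import silhouette_score

from mirsig import featsel, popcompare
from mirsig.io_model import ForestConfig, NormalizedMatrix, read_metadata

ROOT = Path(__file__).resolve().parent.parent / "results"
COHORTS = ("MATCHED-BE", "MATCHED-RW", "REST-BE", "REST-RW")
SEED = 1
TOP_M = 25


def main() -> None:
    out = ROOT / "popcompare"
    out.mkdir(parents=True, exist_ok=True)
    frames, site_of, klass_of = [], {}, {}
    for name in COHORTS:
        df = pd.read_csv(ROOT / "normalized" / f"delta_cq_{name}.csv", index_col=0)
        frames.append(df)
        for r in read_metadata(ROOT / "cohorts" / f"meta_{name}.csv"):
            site_of[r.sample_id] = r.site
            klass_of[r.sample_id] = r.klass
    combined = pd.concat(frames, axis=0)
    nm = NormalizedMatrix(combined, tuple(combined.columns[:1]), "ALL")
    sites = pd.Series({s: site_of[s] for s in nm.sample_ids})

    pca = popcompare.pca_sites(nm)
    sil = silhouette_score(pca.projections.iloc[:, :2], sites[pca.projections.index])
    pca.projections.to_csv(out / "pca_coordinates.csv")
    print(f"PCA: PC1 {pca.explained_variance_ratio[0]:.1%}, "
          f"PC2 {pca.explained_variance_ratio[1]:.1%} of variance; "
          f"site silhouette on PC1-2 = {sil:.2f}")

    cfg = ForestConfig.desk(seed=SEED, n_fs_partitions=15)
    labels = {s: klass_of[s] for s in nm.sample_ids}
    cancer_fs = featsel.rf_importance(nm, labels, cfg)
    cancer_top = featsel.select_features(cancer_fs.table, TOP_M)
    rf_top, _ = popcompare.rf_site_discrimination(nm, sites, cfg, m=TOP_M)
    kw_top, kw_table = popcompare.kruskal_wallis_screen(nm, sites, m=TOP_M)
    kw_table.to_csv(out / "kruskal_wallis.csv")

    flagged = popcompare.confounded_features(cancer_top, rf_top, kw_top)
    popcompare.venn_table(cancer_top, rf_top, kw_top).to_csv(out / "venn.csv")
    pd.Series(sorted(flagged)).to_csv(out / "flagged.csv", index=False, header=["mirna"])
    print(f"top-{TOP_M} sets: cancer/RF-site/KW-site; "
          f"RF-site & KW-site agree on {len(set(rf_top) & set(kw_top))} miRNAs")
    print(f"confounded (triple intersection): {sorted(flagged)}")


if __name__ == "__main__":
    main()
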