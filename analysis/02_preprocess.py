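#!/usr/bin/env python
"""QC and normalize the simulated cohorts (run 01_simulate_cohorts.py first).

Applies the ABS414 > 5 hemolysis exclusion, harmonizes the two site panels to
their common miRNAs, and normalizes every cohort independently against its
own 50 most expressed miRNAs.  Writes delta-Cq matrices and the normalizer
audit under results/normalized/.
"""

from pathlib import Path

import yaml

from mirsig.io_model import CqMatrix, Panel, read_cq_table, read_metadata
from mirsig.preprocess import filter_hemolysis, harmonize_panels, normalize_delta_cq

ROOT = Path(__file__).resolve().parent.parent / "results"
COHORTS = ("MATCHED-BE", "MATCHED-RW", "REST-BE", "REST-RW")


def main() -> None:
    out = ROOT / "normalized"
    out.mkdir(parents=True, exist_ok=True)
    cq = {name: read_cq_table(ROOT / "cohorts" / f"cq_{name}.csv") for name in COHORTS}
    panels = {
        name: Panel(name, tuple(m.mirna_ids)) for name, m in cq.items()
    }
    common = harmonize_panels(panels["MATCHED-BE"], panels["MATCHED-RW"])
    print(f"common panel: {len(common)} miRNAs")

    audit = {}
    for name in COHORTS:
        records = read_metadata(ROOT / "cohorts" / f"meta_{name}.csv")
        kept = filter_hemolysis(records)
        print(f"{name}: {len(records) - len(kept)} hemolysed samples excluded, "
              f"{len(kept)} retained")
        matrix = CqMatrix(
            cq[name].frame.loc[[r.sample_id for r in kept], list(common.mirna_ids)]
        )
        nm = normalize_delta_cq(matrix, n_norm=50, dataset_id=name)
        nm.frame.to_csv(out / f"delta_cq_{name}.csv", na_rep="NA")
        audit[name] = list(nm.normalizer_set)
    (out / "normalizer_audit.yaml").write_text(yaml.safe_dump(audit))
    shared = set.intersection(*(set(v) for v in audit.values()))
    print(f"normalizer sets recomputed per cohort; {len(shared)}/50 shared by all four")


if __name__ == "__main__":
    main()
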