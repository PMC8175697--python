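"""Core domain types and file I/O shared by every pipeline stage.

Conventions
-----------
Cq tables are delimited files with samples as rows and miRNAs as columns
(first column ``sample_id``); a transposed dialect is supported because both
orientations occur in qPCR exports.  Missing (undetected) reactions are
encoded on disk as an empty cell or the token ``NA`` and held in memory as a
boolean presence mask — never as a sentinel Cq value, which would corrupt
normalizer means.  Valid Cq values lie in [0, 50]: a quantification cycle
cannot exceed the run length, and 50 cycles covers standard protocols.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

CQ_MIN = 0.0
CQ_MAX = 50.0

CLASS_LABELS = ("healthy", "cancer")
SUBTYPE_LABELS = ("ER+/HER2-", "ER+/HER2+", "ER-/HER2+", "TN", "NA")

MISSING_TOKENS = {"", "NA", "NaN", "nan", "na"}


class FormatError(ValueError):
    """Structurally malformed input file (duplicates, bad header...)."""


class ValidationError(ValueError):
    """Well-formed input carrying invalid values or labels."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CqMatrix:
    """Samples x miRNAs raw quantification-cycle values.

    ``frame`` holds Cq cycles (lower = more abundant) with NaN wherever a
    reaction was not detected; ``present_mask`` exposes the measured/missing
    distinction explicitly.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.frame = self.frame.astype(float)
        if self.frame.index.has_duplicates:
            dups = self.frame.index[self.frame.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        if self.frame.columns.has_duplicates:
            dups = self.frame.columns[self.frame.columns.duplicated()].tolist()
            raise FormatError(f"duplicate miRNA ids: {dups}")
        values = self.frame.to_numpy()
        bad = np.where(~np.isnan(values) & ((values < CQ_MIN) | (values > CQ_MAX)))
        if bad[0].size:
            s = self.frame.index[bad[0][0]]
            m = self.frame.columns[bad[1][0]]
            raise ValidationError(
                f"Cq outside [{CQ_MIN:g}, {CQ_MAX:g}] at sample {s!r}, miRNA {m!r}: "
                f"{values[bad[0][0], bad[1][0]]}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def present_mask(self) -> pd.DataFrame:
        return self.frame.notna()

    @property
    def n_present(self) -> int:
        return int(self.frame.notna().to_numpy().sum())

    def subset_samples(self, sample_ids: Sequence[str]) -> "CqMatrix":
        return CqMatrix(self.frame.loc[list(sample_ids)].copy())

    def subset_mirnas(self, mirna_ids: Sequence[str]) -> "CqMatrix":
        return CqMatrix(self.frame.loc[:, list(mirna_ids)].copy())


@dataclass
class NormalizedMatrix:
    """Delta-Cq values relative to a per-sample normalizer mean.

    delta_cq(s, m) = Cq(s, m) - mean of sample s's present Cq over
    ``normalizer_set``.  Missing entries stay missing.
    """

    frame: pd.DataFrame
    normalizer_set: tuple[str, ...]
    source_dataset_id: str = ""

    def __post_init__(self) -> None:
        self.normalizer_set = tuple(self.normalizer_set)
        missing = set(self.normalizer_set) - set(self.frame.columns)
        # the normalizer set must come from the source matrix; a harmonized
        # view may later drop columns, so only warn-on-construct is too lax —
        # enforce at construction from preprocess instead.
        vals = self.frame.to_numpy()
        if np.isinf(vals).any():
            raise ValidationError("non-finite delta-Cq value")
        del missing

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def present_mask(self) -> pd.DataFrame:
        return self.frame.notna()

    def subset_samples(self, sample_ids: Sequence[str]) -> "NormalizedMatrix":
        return NormalizedMatrix(
            self.frame.loc[list(sample_ids)].copy(),
            self.normalizer_set,
            self.source_dataset_id,
        )


@dataclass(frozen=True)
class SampleRecord:
    """Per-subject metadata: recruitment site, class, age, molecular subtype,
    hemolysis proxy (plasma absorbance at 414 nm), optional stage/nodes."""

    sample_id: str
    site: str
    klass: str
    age: float
    subtype: str = "NA"
    abs414: float | None = None
    stage: str | None = None
    nodes: str | None = None

    def __post_init__(self) -> None:
        if self.klass not in CLASS_LABELS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown class label {self.klass!r} "
                f"(expected one of {CLASS_LABELS})"
            )
        if self.subtype not in SUBTYPE_LABELS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown subtype {self.subtype!r}"
            )
        if self.abs414 is not None and self.abs414 < 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: negative ABS414 {self.abs414}"
            )


@dataclass(frozen=True)
class Panel:
    """A named qPCR panel: the miRNAs quantifiable at one site."""

    name: str
    mirna_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        ids = tuple(self.mirna_ids)
        if len(set(ids)) != len(ids):
            dups = sorted({m for m in ids if list(ids).count(m) > 1})
            raise FormatError(f"panel {self.name!r}: duplicate miRNA names {dups}")
        object.__setattr__(self, "mirna_ids", ids)

    def __len__(self) -> int:
        return len(self.mirna_ids)

    def __contains__(self, mirna: str) -> bool:
        return mirna in set(self.mirna_ids)


@dataclass(frozen=True)
class Signature:
    """A named, non-empty set of miRNAs feeding one classifier."""

    name: str
    mirna_ids: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mirna_ids", frozenset(self.mirna_ids))
        if not self.mirna_ids:
            raise ValidationError(f"signature {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.mirna_ids)

    @property
    def sorted_members(self) -> tuple[str, ...]:
        return tuple(sorted(self.mirna_ids))


def _default_mtry(p: int) -> int:
    return max(1, math.floor(math.sqrt(p)))


@dataclass
class ForestConfig:
    """Random-forest hyper-parameters shared by selection and search.

    Defaults are the full-scale study settings: ntree = 3000, mtry =
    floor(sqrt(p)), 50 Monte-Carlo design splits at 90% train, 100 feature-
    selection resampling partitions.  ``desk()`` returns a reduced profile
    suitable for interactive runs and the test suite.
    """

    ntree: int = 3000
    mtry_rule: Callable[[int], int] = _default_mtry
    seed: int = 0
    n_design_repeats: int = 50
    train_fraction: float = 0.9
    n_fs_partitions: int = 100

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValidationError(f"ntree must be >= 1, got {self.ntree}")
        if not 0 < self.train_fraction < 1:
            raise ValidationError(
                f"train_fraction must lie in (0, 1), got {self.train_fraction}"
            )

    @classmethod
    def desk(cls, seed: int = 0, **kw) -> "ForestConfig":
        """Reduced profile: ntree=100, 10 design repeats, 25 partitions."""
        base = dict(ntree=100, n_design_repeats=10, n_fs_partitions=25, seed=seed)
        base.update(kw)
        return cls(**base)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_cq_table(path: str | Path, transposed: bool = False) -> CqMatrix:
    """Read a delimited Cq table into a :class:`CqMatrix`.

    First column is ``sample_id`` (or the miRNA name when ``transposed``);
    remaining cells are numeric Cq values, empty, or ``NA``.  Row and column
    order are preserved.
    """
    sep = _sep_for(path)
    with open(path) as fh:
        header = next(csv.reader(fh, delimiter=sep))
    names = header[1:]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise FormatError(f"{path}: duplicated column names {dup}")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = sorted(set(df.index[df.index.duplicated()]))
        raise FormatError(f"{path}: duplicated row names {dup}")
    parsed = df.apply(
        lambda col: pd.to_numeric(
            col.where(~col.astype(str).str.strip().isin(MISSING_TOKENS)),
            errors="raise",
        )
    )
    if transposed:
        parsed = parsed.T
    parsed.index = parsed.index.astype(str)
    parsed.index.name = "sample_id"
    return CqMatrix(parsed)


def write_cq_table(m: CqMatrix, path: str | Path, transposed: bool = False) -> None:
    frame = m.frame.T if transposed else m.frame
    frame.index.name = "mirna_id" if transposed else "sample_id"
    frame.to_csv(path, sep=_sep_for(path), na_rep="NA", float_format="%.6f")


_META_COLUMNS = ["sample_id", "site", "klass", "age", "subtype", "abs414", "stage", "nodes"]


def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Read a sample-metadata table into validated :class:`SampleRecord` s."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if df.empty:
        return []
    required = {"sample_id", "site", "klass", "age"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing metadata columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                site=str(row["site"]),
                klass=str(row["klass"]),
                age=float(row["age"]),
                subtype=str(row.get("subtype", "NA")) if pd.notna(row.get("subtype")) else "NA",
                abs414=float(row["abs414"])
                if "abs414" in df.columns and pd.notna(row["abs414"])
                else None,
                stage=str(row["stage"])
                if "stage" in df.columns and pd.notna(row["stage"])
                else None,
                nodes=str(row["nodes"])
                if "nodes" in df.columns and pd.notna(row["nodes"])
                else None,
            )
        )
    return records


def write_metadata(records: Iterable[SampleRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "site": r.site,
                "klass": r.klass,
                "age": r.age,
                "subtype": r.subtype,
                "abs414": r.abs414,
                "stage": r.stage,
                "nodes": r.nodes,
            }
            for r in records
        ],
        columns=_META_COLUMNS,
    )
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_panel(path: str | Path, name: str | None = None) -> Panel:
    """Panel files hold one miRNA name per line; blank lines ignored."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return Panel(name or Path(path).stem, tuple(ln for ln in lines if ln))


def write_panel(panel: Panel, path: str | Path) -> None:
    Path(path).write_text("\n".join(panel.mirna_ids) + "\n")


PERFORMANCE_COLUMNS = [
    "name",
    "AUC",
    "CI_low",
    "CI_high",
    "cutoff",
    "sensitivity",
    "specificity",
    "n_mirnas",
]


def write_report(results, path: str | Path) -> None:
    """Write a list of SignaturePerformance records as a delimited table.

    Columns follow the validation-report schema (name, AUC, CI bounds,
    Youden cutoff, sensitivity, specificity, signature size).  Values are
    written at full precision so that re-reading reproduces them exactly.
    """
    rows = []
    for r in results:
        rows.append(
            {
                "name": r.signature_name,
                "AUC": repr(float(r.validation_auc)),
                "CI_low": repr(float(r.ci_low)),
                "CI_high": repr(float(r.ci_high)),
                "cutoff": repr(float(r.cutoff)),
                "sensitivity": repr(float(r.sensitivity)),
                "specificity": repr(float(r.specificity)),
                "n_mirnas": r.n_mirnas,
            }
        )
    pd.DataFrame(rows, columns=PERFORMANCE_COLUMNS).to_csv(
        path, sep=_sep_for(path), index=False
    )


def read_report(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path))
    for col in PERFORMANCE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing report column {col!r}")
    return df


def write_config(config: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def read_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


# ---------------------------------------------------------------------------
# published reference signatures
# ---------------------------------------------------------------------------

# Plasma miRNA breast-cancer signatures reported in prior Belgian-cohort
# profiling work: the 8-miRNA signature plus 12 published alternatives with
# comparable design performance.  Useful as ready-made inputs to the
# apply-existing-signatures scenario.
EIGHT_MIR_SIGNATURE = Signature(
    "8-miRNA-signature",
    frozenset(
        {
            "hsa-miR-16-5p",
            "hsa-let-7d-5p",
            "hsa-miR-103a-3p",
            "hsa-miR-107",
            "hsa-miR-148a-3p",
            "hsa-let-7i-5p",
            "hsa-miR-19b-3p",
            "hsa-miR-22-5p",
        }
    ),
)

_ALT = {
    "Signature_1": ["hsa-let-7d-5p", "hsa-miR-16-5p", "hsa-miR-103a-3p", "hsa-miR-199a-5p"],
    "Signature_2": [
        "hsa-let-7d-5p", "hsa-miR-16-5p", "hsa-miR-103a-3p", "hsa-miR-22-3p",
        "hsa-miR-30b-5p",
    ],
    "Signature_3": [
        "hsa-let-7d-5p", "hsa-miR-32-5p", "hsa-miR-199a-5p", "hsa-miR-142-3p",
        "hsa-miR-22-5p",
    ],
    "Signature_4": [
        "hsa-let-7d-5p", "hsa-miR-148a-3p", "hsa-let-7i-5p", "hsa-miR-199a-5p",
        "hsa-miR-451a",
    ],
    "Signature_5": [
        "hsa-let-7d-5p", "hsa-miR-148a-3p", "hsa-let-7f-1-3p", "hsa-miR-199a-5p",
        "hsa-miR-32-5p",
    ],
    "Signature_6": [
        "hsa-miR-16-5p", "hsa-let-7d-5p", "hsa-miR-103a-3p", "hsa-miR-148a-3p",
        "hsa-let-7f-1-3p", "hsa-miR-32-5p",
    ],
    "Signature_7": [
        "hsa-miR-16-5p", "hsa-let-7d-5p", "hsa-let-7i-5p", "hsa-miR-19a-3p",
        "hsa-let-7f-1-3p", "hsa-miR-1-3p",
    ],
    "Signature_8": [
        "hsa-miR-16-5p", "hsa-let-7i-5p", "hsa-miR-19a-3p", "hsa-miR-451a",
        "hsa-miR-19b-3p", "hsa-miR-32-5p",
    ],
    "Signature_9": [
        "hsa-miR-16-5p", "hsa-let-7d-5p", "hsa-miR-103a-3p", "hsa-miR-148a-3p",
        "hsa-miR-19a-3p", "hsa-miR-199a-5p", "hsa-miR-22-3p",
    ],
    "Signature_10": [
        "hsa-miR-16-5p", "hsa-let-7d-5p", "hsa-miR-103a-3p", "hsa-miR-20a-5p",
        "hsa-let-7i-5p", "hsa-miR-1-3p", "hsa-miR-32-5p",
    ],
    "Signature_11": [
        "hsa-miR-16-5p", "hsa-let-7d-5p", "hsa-miR-103a-3p", "hsa-miR-148a-3p",
        "hsa-miR-93-5p", "hsa-miR-451a", "hsa-miR-1-3p", "hsa-miR-22-5p",
    ],
    "Signature_12": [
        "hsa-miR-16-5p", "hsa-let-7d-5p", "hsa-miR-103a-3p", "hsa-miR-20a-5p",
        "hsa-let-7f-1-3p", "hsa-miR-30b-5p", "hsa-miR-590-5p", "hsa-miR-22-3p",
    ],
}

PUBLISHED_SIGNATURES: tuple[Signature, ...] = (EIGHT_MIR_SIGNATURE,) + tuple(
    Signature(name, frozenset(members)) for name, members in _ALT.items()
)
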