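"""Two-site case/control synthetic Cq generator with known ground truth.

The generative model is additive on the Cq scale:

    Cq(s, m) = mu[m] + delta_d[m]*1{s cancer} + delta_s[m]*1{s site B}
               + b_s + eps(s, m)

with a per-sample offset ``b_s ~ Normal(0, sigma_sample)`` standing in for
global loading/extraction efficiency differences (exactly what delta-Cq
normalization removes) and measurement noise ``eps ~ Normal(0, sigma_noise)``.
High Cq values are left-censored at a detection limit ``lod_cq`` (low
abundance goes undetected), and each site measures only its own panel;
panels partially overlap, so some miRNAs exist at one site only.

Disease- and site-effect miRNA sets may overlap: an miRNA shifted both by
disease and by recruitment site is exactly the confounding mechanism that
makes a signature designed at one site degrade at the other.

The default configuration mirrors the two-population study design: cohort
sizes 143/136 (site BE cancer/healthy) and 82/73 (site RW), panels of 187
and 175 miRNAs with 165 in common, five disease miRNAs at -2 Cq of which
two also carry a +2 Cq site shift, and ~8% of samples hemolysed past the
ABS414 > 5 exclusion threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .io_model import CqMatrix, Panel, SampleRecord, ValidationError

# cohort sizes of the two recruitment sites (cancer / healthy)
STUDY_COHORT_SIZES: dict[str, dict[str, int]] = {
    "BE": {"cancer": 143, "healthy": 136},
    "RW": {"cancer": 82, "healthy": 73},
}

STUDY_MATCHED_N = 55  # matched design cohorts: 55 cancers + 55 healthy per site

# molecular-subtype frequencies among the matched cancer patients
SUBTYPE_FREQUENCIES: dict[str, float] = {
    "ER+/HER2-": 26 / 55,
    "ER+/HER2+": 8 / 55,
    "ER-/HER2+": 7 / 55,
    "TN": 14 / 55,
}

# well-characterized plasma miRNAs; kept on both panels so published
# signatures can be applied to simulated cohorts.
KNOWN_PLASMA_MIRNAS: tuple[str, ...] = (
    "hsa-miR-16-5p",
    "hsa-let-7d-5p",
    "hsa-miR-103a-3p",
    "hsa-miR-107",
    "hsa-miR-148a-3p",
    "hsa-let-7i-5p",
    "hsa-miR-19b-3p",
    "hsa-miR-22-5p",
    "hsa-miR-199a-5p",
    "hsa-miR-22-3p",
    "hsa-miR-30b-5p",
    "hsa-miR-32-5p",
    "hsa-miR-142-3p",
    "hsa-miR-451a",
    "hsa-let-7f-1-3p",
    "hsa-miR-19a-3p",
    "hsa-miR-1-3p",
    "hsa-miR-20a-5p",
    "hsa-miR-93-5p",
    "hsa-miR-590-5p",
)

_DEFAULT_N_MIRNAS = 197  # union of the default 187- and 175-miRNA panels
_SHARED_START, _SHARED_END = 22, 187  # universe slice shared by both panels

DEFAULT_DISEASE_EFFECTS: dict[str, float] = {
    "hsa-miR-16-5p": -2.0,
    "hsa-let-7d-5p": -2.0,
    "hsa-miR-103a-3p": -2.0,
    "hsa-miR-148a-3p": -2.0,
    "hsa-let-7i-5p": -2.0,
}

# two of the disease miRNAs also shift with recruitment site (confounded),
# plus 18 site-only miRNAs; all sit on the shared panel slice (names 7122+)
# so the site signal survives panel harmonization
DEFAULT_SITE_EFFECTS: dict[str, float] = {
    "hsa-let-7d-5p": 2.0,
    "hsa-miR-103a-3p": 2.0,
    **{f"hsa-miR-{7122 + i}-3p": 2.0 if i % 2 == 0 else -2.0 for i in range(18)},
}


def default_universe(n_mirnas: int = _DEFAULT_N_MIRNAS) -> tuple[str, ...]:
    """Synthetic miRNA namespace; known plasma miRNAs occupy the shared slice."""
    fill = iter(f"hsa-miR-{7100 + i}-3p" for i in range(n_mirnas))
    names: list[str] = []
    for i in range(n_mirnas):
        if _SHARED_START <= i < _SHARED_START + len(KNOWN_PLASMA_MIRNAS) and n_mirnas >= _SHARED_END:
            names.append(KNOWN_PLASMA_MIRNAS[i - _SHARED_START])
        else:
            names.append(next(fill))
    return tuple(names)


def default_two_site_panels(universe: tuple[str, ...]) -> dict[str, Panel]:
    """187- and 175-miRNA panels overlapping on 165 names."""
    return {
        "BE": Panel("panel-BE-187", universe[:187]),
        "RW": Panel("panel-RW-175", universe[_SHARED_START:197]),
    }


@dataclass
class SimConfig:
    """Ground-truth parameters of one synthetic two-site study."""

    n_per_group_per_site: int | Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: {s: dict(v) for s, v in STUDY_COHORT_SIZES.items()}
    )
    n_mirnas: int = _DEFAULT_N_MIRNAS
    disease_mirnas: Mapping[str, float] | None = None  # name -> delta_d (Cq)
    site_mirnas: Mapping[str, float] | None = None  # name -> delta_s (Cq, site B - site A)
    baseline_mu: Mapping[str, float] | None = None  # name -> mean Cq; drawn if None
    sigma_noise: float = 0.5
    sigma_sample: float = 1.0
    panels: Mapping[str, Panel] | None = None
    hemolysis_shape: float = 2.0  # gamma(shape, scale) for ABS414
    hemolysis_scale: float = 1.2
    lod_cq: float = 37.0
    sites: tuple[str, str] = ("BE", "RW")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_noise < 0 or self.sigma_sample < 0:
            raise ValidationError("noise standard deviations must be >= 0")
        if isinstance(self.n_per_group_per_site, int):
            n = self.n_per_group_per_site
            self.n_per_group_per_site = {
                s: {"cancer": n, "healthy": n} for s in self.sites
            }
        if self.panels is None:
            universe = default_universe(self.n_mirnas)
            if self.n_mirnas == _DEFAULT_N_MIRNAS:
                self.panels = default_two_site_panels(universe)
            else:
                self.panels = {s: Panel(f"panel-{s}", universe) for s in self.sites}
        universe = self.universe
        if self.disease_mirnas is None:
            self.disease_mirnas = {
                m: d for m, d in DEFAULT_DISEASE_EFFECTS.items() if m in universe
            } if self.n_mirnas == _DEFAULT_N_MIRNAS else {}
        if self.site_mirnas is None:
            self.site_mirnas = {
                m: d for m, d in DEFAULT_SITE_EFFECTS.items() if m in universe
            } if self.n_mirnas == _DEFAULT_N_MIRNAS else {}
        for effects, label in ((self.disease_mirnas, "disease"), (self.site_mirnas, "site")):
            stray = set(effects) - universe
            if stray:
                raise ValidationError(f"{label} effect miRNAs outside universe: {sorted(stray)}")
            if not all(np.isfinite(list(effects.values())) if effects else [True]):
                raise ValidationError(f"non-finite {label} effect")

    @property
    def universe(self) -> set[str]:
        out: set[str] = set()
        for panel in self.panels.values():
            out.update(panel.mirna_ids)
        return out

    @property
    def universe_ordered(self) -> list[str]:
        seen: dict[str, None] = {}
        for site in self.sites:
            for m in self.panels[site].mirna_ids:
                seen.setdefault(m)
        return list(seen)


@dataclass
class SimTruth:
    """Record of the injected effects — the oracle for recovery tests."""

    disease_effects: dict[str, float]
    site_effects: dict[str, float]
    baseline_mu: dict[str, float]
    lod_cq: float
    seed: int

    @property
    def disease_set(self) -> set[str]:
        return set(self.disease_effects)

    @property
    def site_set(self) -> set[str]:
        return set(self.site_effects)

    @property
    def confounded_set(self) -> set[str]:
        return self.disease_set & self.site_set

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "disease_effects": self.disease_effects,
                    "site_effects": self.site_effects,
                    "baseline_mu": self.baseline_mu,
                    "lod_cq": self.lod_cq,
                    "seed": self.seed,
                },
                sort_keys=True,
            )
        )


@dataclass
class SimStudy:
    """One simulated two-site study: per-site Cq matrices + metadata + truth."""

    cq: dict[str, CqMatrix]
    records: dict[str, list[SampleRecord]]
    truth: SimTruth

    def all_records(self) -> list[SampleRecord]:
        return [r for site in self.records.values() for r in site]


def _draw_baseline(config: SimConfig, rng: np.random.Generator) -> pd.Series:
    names = config.universe_ordered
    if config.baseline_mu is not None:
        missing = set(names) - set(config.baseline_mu)
        if missing:
            raise ValidationError(f"baseline_mu missing miRNAs: {sorted(missing)[:3]}...")
        return pd.Series({m: float(config.baseline_mu[m]) for m in names})
    return pd.Series(rng.uniform(22.0, 34.0, size=len(names)), index=names)


def generate_study(config: SimConfig) -> SimStudy:
    """Draw one synthetic study from the configured generative model.

    Returns per-site Cq matrices restricted to each site's panel (panel-absent
    miRNAs are unmeasured at that site), sample metadata with ages, subtypes
    and hemolysis levels, and the ground-truth effect record.
    """
    for site, groups in config.n_per_group_per_site.items():
        for klass, n in groups.items():
            if n < 2:
                raise ValidationError(
                    f"n_per_group_per_site[{site}][{klass}] = {n} < 2: "
                    "resampling partitions are impossible"
                )
    rng = np.random.default_rng(config.seed)
    mu = _draw_baseline(config, rng)
    site_b = config.sites[1]

    def subtype_allocation(n: int) -> list[str]:
        # largest-remainder proportional allocation: subtype counts follow the
        # study frequencies exactly, so equally sized sites can be fully
        # subtype-matched (a property of the matched design, not of sampling)
        raw = {k: f * n for k, f in SUBTYPE_FREQUENCIES.items()}
        counts = {k: int(np.floor(v)) for k, v in raw.items()}
        leftovers = sorted(raw, key=lambda k: (raw[k] - counts[k], k), reverse=True)
        for k in leftovers[: n - sum(counts.values())]:
            counts[k] += 1
        return [k for k, c in counts.items() for _ in range(c)]

    cq_out: dict[str, CqMatrix] = {}
    rec_out: dict[str, list[SampleRecord]] = {}
    for site in config.sites:
        panel = config.panels[site]
        cols = list(panel.mirna_ids)
        base = mu[cols].to_numpy()
        delta_d = np.array([config.disease_mirnas.get(m, 0.0) for m in cols])
        delta_s = np.array([config.site_mirnas.get(m, 0.0) for m in cols]) * (
            1.0 if site == site_b else 0.0
        )
        rows, ids, records = [], [], []
        for klass in ("cancer", "healthy"):
            n = config.n_per_group_per_site[site][klass]
            offsets = rng.normal(0.0, config.sigma_sample, size=n)
            noise = rng.normal(0.0, config.sigma_noise, size=(n, len(cols)))
            vals = base + delta_d * (klass == "cancer") + delta_s + offsets[:, None] + noise
            rows.append(vals)
            abs414 = rng.gamma(config.hemolysis_shape, config.hemolysis_scale, size=n)
            ages = rng.integers(27, 69, size=n)
            subtypes = (
                rng.permutation(subtype_allocation(n))
                if klass == "cancer"
                else ["NA"] * n
            )
            for i in range(n):
                sid = f"{site}-{klass[0].upper()}{i:03d}"
                ids.append(sid)
                records.append(
                    SampleRecord(
                        sample_id=sid,
                        site=site,
                        klass=klass,
                        age=float(ages[i]),
                        subtype=str(subtypes[i]),
                        abs414=float(abs414[i]),
                    )
                )
        values = np.clip(np.vstack(rows), 0.0, 50.0)
        values[values > config.lod_cq] = np.nan  # below detection limit
        frame = pd.DataFrame(values, index=ids, columns=cols)
        frame.index.name = "sample_id"
        cq_out[site] = CqMatrix(frame)
        rec_out[site] = records

    truth = SimTruth(
        disease_effects=dict(config.disease_mirnas),
        site_effects=dict(config.site_mirnas),
        baseline_mu={m: float(v) for m, v in mu.items()},
        lod_cq=config.lod_cq,
        seed=config.seed,
    )
    return SimStudy(cq=cq_out, records=rec_out, truth=truth)


@dataclass
class Cohort:
    """A named cohort: Cq matrix plus the matching metadata records."""

    name: str
    cq: CqMatrix
    records: list[SampleRecord]

    @property
    def labels(self) -> pd.Series:
        return pd.Series({r.sample_id: r.klass for r in self.records})


def generate_matched_rest(
    config: SimConfig, matched_n: int = STUDY_MATCHED_N
) -> tuple[dict[str, Cohort], SimTruth]:
    """Split each simulated site into MATCHED (cross-site age/subtype/count
    matched, ``matched_n`` per class per site) and REST cohorts.

    The four cohorts are named ``MATCHED-<site>`` and ``REST-<site>``; the
    MATCHED pair serves as design material, the REST pair as independent
    validation material.  Subsets are disjoint and exhaustive per site.
    """
    from .preprocess import match_cohorts  # local import: avoids a cycle

    study = generate_study(config)
    site_a, site_b = config.sites
    for site in config.sites:
        for klass in ("cancer", "healthy"):
            if matched_n > config.n_per_group_per_site[site][klass]:
                raise ValidationError(
                    f"matched_n={matched_n} exceeds {site}/{klass} group size "
                    f"{config.n_per_group_per_site[site][klass]}"
                )

    matched_ids: dict[str, set[str]] = {site_a: set(), site_b: set()}
    if matched_n > 0:
        pairs, _, _ = match_cohorts(study.records[site_a], study.records[site_b])
        for klass in ("cancer", "healthy"):
            kl_pairs = [p for p in pairs if p[0].klass == klass]
            kl_pairs.sort(
                key=lambda p: (abs(p[0].age - p[1].age), p[0].sample_id, p[1].sample_id)
            )
            if len(kl_pairs) < matched_n:
                raise ValidationError(
                    f"only {len(kl_pairs)} cross-site {klass} pairs available; "
                    f"matched_n={matched_n} requested"
                )
            for a, b in kl_pairs[:matched_n]:
                matched_ids[site_a].add(a.sample_id)
                matched_ids[site_b].add(b.sample_id)

    cohorts: dict[str, Cohort] = {}
    for site in config.sites:
        recs = study.records[site]
        chosen = matched_ids[site]
        matched_recs = [r for r in recs if r.sample_id in chosen]
        rest_recs = [r for r in recs if r.sample_id not in chosen]
        cohorts[f"MATCHED-{site}"] = Cohort(
            f"MATCHED-{site}",
            study.cq[site].subset_samples([r.sample_id for r in matched_recs])
            if matched_recs
            else CqMatrix(study.cq[site].frame.iloc[:0]),
            matched_recs,
        )
        cohorts[f"REST-{site}"] = Cohort(
            f"REST-{site}",
            study.cq[site].subset_samples([r.sample_id for r in rest_recs]),
            rest_recs,
        )
    return cohorts, study.truth
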