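"""Shared fixtures: small synthetic studies and matrix builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mirsig.io_model import CqMatrix, ForestConfig, NormalizedMatrix
from mirsig.simdata import SimConfig, generate_matched_rest


def make_cq(values, samples=None, mirnas=None) -> CqMatrix:
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{i}" for i in range(values.shape[0])]
    mirnas = mirnas or [f"hsa-miR-{100 + j}-5p" for j in range(values.shape[1])]
    frame = pd.DataFrame(values, index=samples, columns=mirnas)
    frame.index.name = "sample_id"
    return CqMatrix(frame)


def make_nm(values, samples=None, mirnas=None, normalizers=()) -> NormalizedMatrix:
    cq = make_cq(values, samples, mirnas)
    return NormalizedMatrix(cq.frame, tuple(normalizers) or tuple(cq.mirna_ids[:1]))


def planted_disease_config(
    n_disease: int = 5,
    delta_d: float = -3.0,
    n_mirnas: int = 40,
    n_per_group: int = 50,
    sigma_noise: float = 0.5,
    seed: int = 0,
    site_mirnas: dict | None = None,
) -> SimConfig:
    disease = {f"hsa-miR-{7100 + i}-3p": delta_d for i in range(n_disease)}
    return SimConfig(
        n_per_group_per_site=n_per_group,
        n_mirnas=n_mirnas,
        disease_mirnas=disease,
        site_mirnas=site_mirnas or {},
        sigma_noise=sigma_noise,
        sigma_sample=1.0,
        lod_cq=50.0,  # no censoring: planted features must stay complete
        seed=seed,
    )


def labels_of(records) -> dict[str, str]:
    return {r.sample_id: r.klass for r in records}


@pytest.fixture(scope="session")
def tiny_forest_cfg() -> ForestConfig:
    return ForestConfig.desk(seed=0, ntree=60, n_design_repeats=5, n_fs_partitions=8)


@pytest.fixture(scope="session")
def planted_cohorts():
    """One planted-effect two-site study reused by several tests."""
    cfg = planted_disease_config(n_disease=4, delta_d=-3.0, n_mirnas=30, n_per_group=40, seed=11)
    cohorts, truth = generate_matched_rest(cfg, matched_n=25)
    return cohorts, truth
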