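"""QC, panel harmonization, delta-Cq normalization, cohort matching."""

import numpy as np
import pandas as pd
import pytest

from mirsig.io_model import Panel, SampleRecord, ValidationError
from mirsig.preprocess import (
    filter_hemolysis,
    harmonize_panels,
    match_cohorts,
    normalize_delta_cq,
    select_top_expressed,
)
from mirsig.simdata import SimConfig, default_two_site_panels, default_universe, generate_study

from conftest import make_cq


def _rec(sid, klass="healthy", abs414=None, age=40.0, subtype="NA", site="BE"):
    return SampleRecord(sample_id=sid, site=site, klass=klass, age=age,
                        subtype=subtype, abs414=abs414)


class TestHemolysisFilter:
    def test_exclusion_is_strictly_greater_than(self):
        records = [_rec("a", abs414=4.9), _rec("b", abs414=5.0), _rec("c", abs414=5.1)]
        kept = filter_hemolysis(records)
        assert [r.sample_id for r in kept] == ["a", "b"]  # boundary retained

    def test_hemolysed_sample_excluded(self):
        assert filter_hemolysis([_rec("x", abs414=6.2)]) == []

    def test_missing_abs414_passes_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            kept = filter_hemolysis([_rec("x", abs414=None)])
        assert len(kept) == 1 and "ABS414" in caplog.text

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValidationError):
            filter_hemolysis([], threshold=-1.0)


class TestHarmonizePanels:
    def test_identical_panels_unchanged(self):
        p = Panel("p", ("x", "y"))
        assert harmonize_panels(p, p).mirna_ids == ("x", "y")

    def test_intersection_preserves_first_order(self):
        a, b = Panel("a", ("x", "y", "z")), Panel("b", ("y", "z", "w"))
        assert harmonize_panels(a, b).mirna_ids == ("y", "z")
        assert harmonize_panels(b, a).mirna_ids == ("y", "z")

    def test_default_simulated_panels_share_165(self):
        panels = default_two_site_panels(default_universe())
        assert len(harmonize_panels(panels["BE"], panels["RW"])) == 165

    def test_disjoint_panels_rejected(self):
        with pytest.raises(ValidationError):
            harmonize_panels(Panel("a", ("x",)), Panel("b", ("y",)))


class TestTopExpressed:
    def test_lowest_mean_cq_wins(self):
        m = make_cq([[20, 25, 30, 35], [20, 25, 30, 35]],
                    mirnas=["m1", "m2", "m3", "m4"])
        assert select_top_expressed(m, 2) == ("m1", "m2")

    def test_n_norm_equals_all(self):
        m = make_cq([[20, 25], [22, 23]], mirnas=["m1", "m2"])
        assert set(select_top_expressed(m, 2)) == {"m1", "m2"}

    def test_tie_at_cut_broken_lexicographically(self):
        m = make_cq([[20.0, 25.0, 25.0]], mirnas=["m1", "mB", "mA"])
        assert select_top_expressed(m, 2) == ("m1", "mA")

    def test_missing_excluded_from_ranking_mean(self):
        # m2's only present value (18) beats m1's mean of 20
        m = make_cq([[20.0, 18.0], [20.0, np.nan]], mirnas=["m1", "m2"])
        assert select_top_expressed(m, 1) == ("m2",)

    def test_too_few_candidates_rejected(self):
        m = make_cq([[20.0, np.nan]], mirnas=["m1", "m2"])
        with pytest.raises(ValidationError):
            select_top_expressed(m, 2)


class TestNormalizeDeltaCq:
    def test_delta_is_cq_minus_normalizer_mean(self):
        m = make_cq([[30.0, 30.0, 33.0]], mirnas=["n1", "n2", "t"])
        nm = normalize_delta_cq(m, normalizer_set=("n1", "n2"))
        assert nm.frame.loc["s0", "t"] == pytest.approx(3.0)
        assert nm.frame.loc["s0", "n1"] == pytest.approx(0.0)

    def test_per_sample_shift_cancels(self):
        base = np.array([[28.0, 30.0, 33.0], [27.0, 29.0, 31.0]])
        shifted = base.copy()
        shifted[0] += 2.5  # constant offset on one sample
        kw = dict(mirnas=["n1", "n2", "t"])
        nm_a = normalize_delta_cq(make_cq(base, **kw), normalizer_set=("n1", "n2"))
        nm_b = normalize_delta_cq(make_cq(shifted, **kw), normalizer_set=("n1", "n2"))
        pd.testing.assert_frame_equal(nm_a.frame, nm_b.frame)

    def test_missing_entries_stay_missing(self):
        m = make_cq([[30.0, 30.0, np.nan]], mirnas=["n1", "n2", "t"])
        nm = normalize_delta_cq(m, normalizer_set=("n1", "n2"))
        assert np.isnan(nm.frame.loc["s0", "t"])

    def test_sample_without_normalizer_cq_named(self):
        m = make_cq([[np.nan, np.nan, 30.0], [28.0, 29.0, 30.0]],
                    samples=["dead", "ok"], mirnas=["n1", "n2", "t"])
        with pytest.raises(ValidationError, match="dead"):
            normalize_delta_cq(m, normalizer_set=("n1", "n2"))

    def test_sample_offsets_exactly_removed_on_simulated_data(self):
        """Per-sample mean delta-Cq over the normalizer set is identically 0."""
        cfg = SimConfig(n_per_group_per_site=15, n_mirnas=30, disease_mirnas={},
                        site_mirnas={}, sigma_sample=2.0, lod_cq=50.0, seed=3)
        study = generate_study(cfg)
        nm = normalize_delta_cq(study.cq["BE"], n_norm=10)
        ref = nm.frame.loc[:, list(nm.normalizer_set)]
        assert np.abs(ref.mean(axis=1, skipna=True).to_numpy()).max() < 1e-12

    def test_qc_and_harmonization_commute(self):
        """Hemolysis filtering before vs after panel harmonization is identical."""
        cfg = SimConfig(n_per_group_per_site=15, seed=5)
        study = generate_study(cfg)
        panels = cfg.panels
        common = harmonize_panels(panels["BE"], panels["RW"])
        cq = study.cq["BE"]
        records = study.records["BE"]
        kept_ids = [r.sample_id for r in filter_hemolysis(records)]
        a = cq.subset_samples(kept_ids).subset_mirnas(common.mirna_ids)
        b = cq.subset_mirnas(common.mirna_ids).subset_samples(kept_ids)
        na = normalize_delta_cq(a, n_norm=20)
        nb = normalize_delta_cq(b, n_norm=20)
        pd.testing.assert_frame_equal(na.frame, nb.frame)
        assert na.normalizer_set == nb.normalizer_set


class TestMatchCohorts:
    def test_identical_rosters_fully_matched(self):
        a = [_rec(f"a{i}", age=30 + i, site="BE") for i in range(4)]
        b = [_rec(f"b{i}", age=30 + i, site="RW") for i in range(4)]
        pairs, left_a, left_b = match_cohorts(a, b)
        assert len(pairs) == 4 and not left_a and not left_b
        assert all(pa.age == pb.age for pa, pb in pairs)

    def test_greedy_min_age_difference(self):
        a = [_rec("a40", "cancer", age=40, subtype="TN"),
             _rec("a50", "cancer", age=50, subtype="TN")]
        b = [_rec("b41", "cancer", age=41, subtype="TN", site="RW"),
             _rec("b60", "cancer", age=60, subtype="TN", site="RW")]
        pairs, _, _ = match_cohorts(a, b)
        assert {(p[0].sample_id, p[1].sample_id) for p in pairs} == {
            ("a40", "b41"), ("a50", "b60")
        }

    def test_matched_counts_equal_per_class_and_stratum(self):
        rng = np.random.default_rng(0)
        a = [_rec(f"a{i}", klass=("cancer" if i % 2 else "healthy"),
                  subtype=("TN" if i % 2 else "NA"), age=float(rng.integers(30, 60)))
             for i in range(10)]
        b = [_rec(f"b{i}", klass=("cancer" if i % 3 == 0 else "healthy"),
                  subtype=("TN" if i % 3 == 0 else "NA"),
                  age=float(rng.integers(30, 60)), site="RW")
             for i in range(9)]
        pairs, _, _ = match_cohorts(a, b)
        for klass in ("cancer", "healthy"):
            na = sum(p[0].klass == klass for p in pairs)
            nb = sum(p[1].klass == klass for p in pairs)
            assert na == nb

    def test_one_sided_stratum_left_unmatched(self, caplog):
        a = [_rec("a0", "cancer", age=40, subtype="TN")]
        b = [_rec("b0", "cancer", age=40, subtype="ER+/HER2-", site="RW")]
        with caplog.at_level("WARNING"):
            pairs, left_a, left_b = match_cohorts(a, b)
        assert not pairs and len(left_a) == 1 and len(left_b) == 1
        assert "stratum" in caplog.text
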