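"""Between-site comparison: PCA separation, KW screen, confounder flagging."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import silhouette_score

from mirsig.io_model import ForestConfig, NormalizedMatrix, ValidationError
from mirsig.popcompare import (
    confounded_features,
    exclude_features,
    kruskal_wallis_screen,
    pca_sites,
    rf_site_discrimination,
    venn_table,
)


def _two_site_nm(n_per_site=30, n_features=100, n_shifted=30, delta=3.0,
                 sigma=0.5, seed=0):
    rng = np.random.default_rng(seed)
    features = [f"hsa-miR-{i:03d}-5p" for i in range(n_features)]
    base = rng.normal(0, sigma, (2 * n_per_site, n_features))
    base[n_per_site:, :n_shifted] += delta  # site B offset
    ids = [f"A{i}" for i in range(n_per_site)] + [f"B{i}" for i in range(n_per_site)]
    sites = pd.Series(["A"] * n_per_site + ["B"] * n_per_site, index=ids)
    nm = NormalizedMatrix(pd.DataFrame(base, index=ids, columns=features),
                          (features[0],))
    return nm, sites, features[:n_shifted]


class TestPca:
    def test_site_offset_separates_on_leading_components(self):
        nm, sites, _ = _two_site_nm()
        res = pca_sites(nm)
        s = silhouette_score(res.projections.iloc[:, :2], sites[res.projections.index])
        assert s > 0.3

    def test_shuffled_labels_show_no_separation(self):
        nm, sites, _ = _two_site_nm(seed=1)
        rng = np.random.default_rng(2)
        shuffled = pd.Series(rng.permutation(sites.to_numpy()), index=sites.index)
        res = pca_sites(nm)
        s = silhouette_score(res.projections.iloc[:, :2], shuffled[res.projections.index])
        assert abs(s) < 0.1

    def test_explained_variance_nonincreasing_and_bounded(self):
        nm, _, _ = _two_site_nm(seed=3)
        res = pca_sites(nm)
        evr = res.explained_variance_ratio
        assert (np.diff(evr) <= 1e-12).all()
        assert evr.sum() <= 1.0 + 1e-9

    def test_sample_reordering_invariant_up_to_sign(self):
        nm, _, _ = _two_site_nm(n_per_site=10, n_features=20, seed=4)
        res_a = pca_sites(nm)
        perm = list(reversed(nm.sample_ids))
        res_b = pca_sites(nm.subset_samples(perm))
        for pc in ("PC1", "PC2"):
            a = res_a.projections.loc[perm, pc].to_numpy()
            b = res_b.projections[pc].to_numpy()
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)

    def test_missing_features_dropped_with_warning(self, caplog):
        nm, _, _ = _two_site_nm(n_per_site=5, n_features=10, seed=5)
        frame = nm.frame.copy()
        frame.iloc[0, 0] = np.nan
        with caplog.at_level("WARNING"):
            res = pca_sites(NormalizedMatrix(frame, nm.normalizer_set))
        assert res.dropped_features == (nm.mirna_ids[0],)

    def test_too_few_features_rejected(self):
        nm = NormalizedMatrix(
            pd.DataFrame({"m": [1.0, 2.0, 3.0]}, index=["a", "b", "c"]), ("m",)
        )
        with pytest.raises(ValidationError):
            pca_sites(nm)


class TestKruskalWallis:
    def test_two_group_closed_form(self):
        # {1,2,3} vs {10,11,12}: H = 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1) = 3.857...
        frame = pd.DataFrame({"m1": [1, 2, 3, 10, 11, 12],
                              "m2": [5, 6, 7, 5.5, 6.5, 7.5]},
                             index=list("abcdef"), dtype=float)
        nm = NormalizedMatrix(frame, ("m1",))
        sites = pd.Series(["A"] * 3 + ["B"] * 3, index=list("abcdef"))
        _, table = kruskal_wallis_screen(nm, sites, m=2)
        assert table.loc["m1", "H"] == pytest.approx(12 / 42 * (36 + 225) / 3 - 21)
        assert table.loc["m1", "H"] == pytest.approx(3.857142857, abs=1e-6)

    def test_identical_distributions_give_zero_h(self):
        frame = pd.DataFrame({"m1": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0], "m2": [0.0] * 6},
                             index=list("abcdef"))
        nm = NormalizedMatrix(frame, ("m1",))
        sites = pd.Series(["A"] * 3 + ["B"] * 3, index=list("abcdef"))
        _, table = kruskal_wallis_screen(nm, sites, m=2)
        assert table.loc["m1", "H"] == pytest.approx(0.0)

    def test_constant_feature_kept_with_warning(self, caplog):
        frame = pd.DataFrame({"m1": [1.0, 2.0, 3.0, 4.0], "flat": [2.0] * 4},
                             index=list("abcd"))
        nm = NormalizedMatrix(frame, ("m1",))
        sites = pd.Series(["A", "A", "B", "B"], index=list("abcd"))
        with caplog.at_level("WARNING"):
            top, table = kruskal_wallis_screen(nm, sites, m=2)
        assert table.loc["flat", "H"] == 0.0 and table.loc["flat", "p"] == 1.0
        assert "constant" in caplog.text

    def test_planted_site_features_take_smallest_p(self):
        nm, sites, shifted = _two_site_nm(n_per_site=20, n_features=40,
                                          n_shifted=5, delta=2.0, seed=6)
        top, _ = kruskal_wallis_screen(nm, sites, m=5)
        assert set(top) == set(shifted)

    def test_monotone_in_group_separation(self):
        medians = []
        for delta in (0.5, 1.5, 3.0):
            nm, sites, shifted = _two_site_nm(n_per_site=15, n_features=30,
                                              n_shifted=5, delta=delta, seed=7)
            _, table = kruskal_wallis_screen(nm, sites, m=5)
            medians.append(table.loc[shifted, "p"].median())
        assert medians[0] > medians[1] > medians[2]


class TestRfSiteDiscrimination:
    def test_planted_site_features_recovered_and_deterministic(self):
        nm, sites, shifted = _two_site_nm(n_per_site=25, n_features=30,
                                          n_shifted=4, delta=3.0, seed=8)
        cfg = ForestConfig.desk(ntree=50, n_fs_partitions=6, seed=0)
        top_a, _ = rf_site_discrimination(nm, sites, cfg, m=4)
        top_b, _ = rf_site_discrimination(nm, sites, cfg, m=4)
        assert set(top_a) == set(shifted)
        assert top_a == top_b

    def test_m_of_n_features_returns_full_ranking(self):
        nm, sites, _ = _two_site_nm(n_per_site=10, n_features=12, n_shifted=3, seed=9)
        top, _ = rf_site_discrimination(
            nm, sites, ForestConfig.desk(ntree=30, n_fs_partitions=4), m=12
        )
        assert set(top) == set(nm.mirna_ids)


class TestConfoundedFeatures:
    def test_disjoint_sets_flag_nothing(self):
        assert confounded_features({"a"}, {"b"}, {"c"}) == set()

    def test_triple_intersection(self):
        assert confounded_features({"a", "b", "c"}, {"b", "c", "d"}, {"c", "e"}) == {"c"}

    def test_union_rule_is_stricter(self):
        got = confounded_features({"a", "b", "c"}, {"b"}, {"c"}, rule="union")
        assert got == {"b", "c"}

    def test_symmetric_in_site_sets_and_idempotent(self):
        cancer, s1, s2 = {"a", "b", "c"}, {"b", "c"}, {"c", "d"}
        flagged = confounded_features(cancer, s1, s2)
        assert flagged == confounded_features(cancer, s2, s1)
        assert confounded_features(flagged, s1, s2) == flagged

    def test_venn_table_membership(self):
        df = venn_table({"a", "c"}, {"b", "c"}, {"c"})
        assert df.loc["c"].all()
        assert df.loc["a", "cancer"] and not df.loc["a", "rf_site"]


class TestExcludeFeatures:
    def _nm(self):
        frame = pd.DataFrame(np.arange(20.0).reshape(2, 10),
                             index=["s1", "s2"],
                             columns=[f"m{i}" for i in range(10)])
        return NormalizedMatrix(frame, ("m0",))

    def test_empty_flag_set_is_identity(self):
        nm = self._nm()
        out = exclude_features(nm, set())
        pd.testing.assert_frame_equal(out.frame, nm.frame)

    def test_values_untouched_after_exclusion(self):
        nm = self._nm()
        out = exclude_features(nm, {"m3", "m7"})
        assert len(out.mirna_ids) == 8
        pd.testing.assert_frame_equal(out.frame, nm.frame.drop(columns=["m3", "m7"]))

    def test_unknown_flags_ignored_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = exclude_features(self._nm(), {"m1", "not-there"})
        assert len(out.mirna_ids) == 9

    def test_exclusion_leaving_too_few_features_rejected(self):
        with pytest.raises(ValidationError):
            exclude_features(self._nm(), {f"m{i}" for i in range(9)})
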