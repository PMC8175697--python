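"""AUC, DeLong CI, ROC curve, Youden cutoff, ensemble validation."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from mirsig.io_model import ForestConfig, Signature, ValidationError
from mirsig.preprocess import normalize_delta_cq
from mirsig.sigsearch import evaluate_signature_design
from mirsig.simdata import generate_matched_rest
from mirsig.valroc import (
    DiscardEvent,
    auc,
    auc_ci,
    predict_ensemble,
    roc_curve,
    trapezoidal_auc,
    validate_signature,
    youden_cutoff,
)

from conftest import labels_of, planted_disease_config


def _toy(rng, n=15, ties=False):
    scores = rng.integers(0, 8, n) / 8.0 if ties else rng.random(n)
    y = np.array([0, 1] * (n // 2) + [0] * (n % 2))
    return scores, y


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_hand_enumerated_pairs(self):
        # cancer {0.8, 0.4} vs healthy {0.6, 0.2}: 3 wins of 4 pairs
        assert auc([0.8, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == 0.75

    def test_matches_sklearn_on_random_toys(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            scores, y = _toy(rng, ties=bool(rng.integers(2)))
            assert auc(scores, y) == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            auc([0.1, 0.2], [1, 1])

    def test_sign_flip_and_monotone_invariance(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            scores, y = _toy(rng)
            a = auc(scores, y)
            assert auc(-scores, y) == pytest.approx(1.0 - a, abs=1e-12)
            assert auc(np.exp(3 * scores), y) == pytest.approx(a, abs=1e-12)


class TestRocCurve:
    def test_perfect_curve_passes_through_corner(self):
        pts = roc_curve([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert any(np.allclose(p, (0.0, 1.0)) for p in pts)
        assert np.allclose(pts[0], (0, 0)) and np.allclose(pts[-1], (1, 1))

    def test_monotone_coordinates(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            scores, y = _toy(rng, ties=True)
            pts = roc_curve(scores, y)
            assert (np.diff(pts[:, 0]) >= -1e-15).all()
            assert (np.diff(pts[:, 1]) >= -1e-15).all()

    def test_four_score_staircase_matches_hand_enumeration(self):
        # cancer {0.8, 0.4}, healthy {0.6, 0.2}; thresholds sweep high->low
        pts = roc_curve([0.8, 0.4, 0.6, 0.2], [1, 1, 0, 0])
        expected = [(0, 0), (0, 0.5), (0.5, 0.5), (0.5, 1.0), (1.0, 1.0)]
        assert [tuple(p) for p in pts] == expected

    def test_trapezoid_equals_mann_whitney(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            scores, y = _toy(rng)  # tie-free
            pts = roc_curve(scores, y)
            assert trapezoidal_auc(pts) == pytest.approx(auc(scores, y), abs=1e-12)


class TestYouden:
    def test_perfect_separation_full_j(self):
        cut, sens, spec = youden_cutoff([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert sens == 1.0 and spec == 1.0
        assert 0.2 < cut < 0.8

    def test_hand_computed_optimum_prefers_high_cutoff(self):
        # cancer {0.9, 0.8, 0.4}, healthy {0.6, 0.3, 0.2}: max J = 2/3 at two
        # cutoffs; the tie resolves to the higher one (between 0.6 and 0.8)
        cut, sens, spec = youden_cutoff([0.9, 0.8, 0.4, 0.6, 0.3, 0.2],
                                        [1, 1, 1, 0, 0, 0])
        assert sens == pytest.approx(2 / 3)
        assert spec == 1.0
        assert 0.6 < cut < 0.8

    def test_identical_scores_give_zero_j(self):
        cut, sens, spec = youden_cutoff([0.5] * 4, [1, 1, 0, 0])
        assert sens + spec - 1.0 == pytest.approx(0.0)

    def test_matches_exhaustive_scan_on_random_toys(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            scores, y = _toy(rng, n=12, ties=bool(rng.integers(2)))
            cut, sens, spec = youden_cutoff(scores, y)
            pos, neg = scores[y == 1], scores[y == 0]
            # independent oracle: scan every score value and +-inf directly
            best_j = max(
                np.mean(pos >= t) + np.mean(neg < t) - 1.0
                for t in np.concatenate([scores, [-np.inf, np.inf]])
            )
            assert sens + spec - 1.0 == pytest.approx(best_j, abs=1e-12)


class TestDeLong:
    def test_interval_contains_point_and_clips(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            scores, y = _toy(rng, n=20)
            lo, hi = auc_ci(scores, y)
            a = auc(scores, y)
            assert lo - 1e-12 <= a <= hi + 1e-12
            assert 0.0 <= lo <= hi <= 1.0

    def test_perfect_separation_upper_bound_clipped_to_one(self):
        scores = np.concatenate([np.ones(20), np.zeros(20)])
        y = np.concatenate([np.ones(20, int), np.zeros(20, int)])
        lo, hi = auc_ci(scores, y)
        assert hi == 1.0

    def test_all_tied_scores_give_wide_interval(self, caplog):
        with caplog.at_level("WARNING"):
            lo, hi = auc_ci([0.5] * 8, [1, 1, 1, 1, 0, 0, 0, 0])
        assert (lo, hi) == (0.0, 1.0)

    def test_coverage_at_true_auc_080(self):
        """Monte-Carlo coverage of the 95% interval at binormal AUC 0.8."""
        delta = np.sqrt(2) * 0.8416212335729143  # sqrt(2) * Phi^-1(0.8)
        rng = np.random.default_rng(6)
        covered = 0
        n_sim = 200
        for _ in range(n_sim):
            pos = rng.normal(delta, 1, 40)
            neg = rng.normal(0, 1, 40)
            scores = np.concatenate([pos, neg])
            y = np.concatenate([np.ones(40, int), np.zeros(40, int)])
            lo, hi = auc_ci(scores, y)
            covered += lo <= 0.8 <= hi
        assert 0.90 * n_sim <= covered <= 0.99 * n_sim


@pytest.fixture(scope="module")
def planted_ensemble():
    cfg = planted_disease_config(n_disease=3, delta_d=-3.0, n_mirnas=20,
                                 n_per_group=40, seed=41)
    cohorts, truth = generate_matched_rest(cfg, matched_n=25)
    design = cohorts["MATCHED-BE"]
    nm = normalize_delta_cq(design.cq, n_norm=8, dataset_id="design")
    ens = evaluate_signature_design(
        Signature("truth", frozenset(truth.disease_set)),
        nm, labels_of(design.records),
        ForestConfig.desk(ntree=60, n_design_repeats=6, seed=0),
    )
    val = cohorts["REST-BE"]
    nm_val = normalize_delta_cq(val.cq, n_norm=8, dataset_id="REST-BE")
    return ens, nm_val, labels_of(val.records)


class TestEnsembleValidation:
    def test_scores_in_unit_interval_one_per_sample(self, planted_ensemble):
        ens, nm_val, _ = planted_ensemble
        scores = predict_ensemble(ens, nm_val)
        assert list(scores.index) == nm_val.sample_ids
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_saturated_ensemble_scores_one(self, planted_ensemble):
        """Deep in the cancer region every tree votes cancer: score = 1."""
        ens, nm_val, _ = planted_ensemble
        extreme = nm_val.frame.iloc[:2].copy()
        extreme.loc[:, list(ens.feature_order)] = -30.0  # far below any healthy profile
        from mirsig.io_model import NormalizedMatrix
        scores = predict_ensemble(ens, NormalizedMatrix(extreme, nm_val.normalizer_set))
        assert (scores == 1.0).all()

    def test_missing_panel_mirna_triggers_discard(self, planted_ensemble):
        ens, nm_val, _ = planted_ensemble
        from mirsig.io_model import NormalizedMatrix
        reduced = NormalizedMatrix(
            nm_val.frame.drop(columns=[ens.feature_order[0]]),
            tuple(m for m in nm_val.normalizer_set if m != ens.feature_order[0]),
            "REST-X",
        )
        out = predict_ensemble(ens, reduced)
        assert isinstance(out, DiscardEvent)
        assert ens.feature_order[0] in out.missing_mirnas
        assert "discarded" in out.reason

    def test_same_site_validation_recovers_signal(self, planted_ensemble):
        ens, nm_val, labels = planted_ensemble
        perf = validate_signature(ens, nm_val, labels, cohort_id="REST-BE")
        assert perf.validation_auc >= 0.9
        assert perf.ci_low <= perf.validation_auc <= perf.ci_high
        assert perf.cohort_id == "REST-BE"
        # operating point is computed from the same scores
        pos = perf.scores[perf.klass_labels == "cancer"]
        neg = perf.scores[perf.klass_labels == "healthy"]
        assert perf.sensitivity == pytest.approx(np.mean(pos >= perf.cutoff))
        assert perf.specificity == pytest.approx(np.mean(neg < perf.cutoff))
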