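"""Evaluation statistics: confusion matrix, malignant probability, ROC,
Mann-Whitney, Cohen's kappa — each checked against an independent oracle."""

import math

import numpy as np
import pytest

from mpmbreast import evaluate as ev
from mpmbreast.errors import DataError, GeometryError, InvalidConfigError


def pair_count_auc(pos_scores, neg_scores) -> float:
    """Brute-force concordant-pair AUC: (concordant + ties/2) / (n1*n2)."""
    wins = ties = 0
    for p in pos_scores:
        for n in neg_scores:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos_scores) * len(neg_scores))


def _verdicts(pos_scores, neg_scores):
    out = []
    for i, s in enumerate(pos_scores):
        out.append(ev.ImageVerdict(f"c{i}", s, "malignant", "cancerous"))
    for i, s in enumerate(neg_scores):
        out.append(ev.ImageVerdict(f"n{i}", s, "nonmalignant", "normal"))
    return out


class _T:
    def __init__(self, truth, blank=False, score=None):
        self.truth_label = truth
        self.is_blank = blank
        self.score = score


class TestTileOutcomes:
    def test_all_blank_image_with_normal_truth_is_tn(self):
        tiles = [_T("no_cancer", blank=True) for _ in range(64)]
        cm = ev.tile_outcomes(tiles)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (0, 0, 0, 64)

    def test_all_blank_image_with_cancer_truth_is_fn(self):
        tiles = [_T("cancer", blank=True) for _ in range(64)]
        cm = ev.tile_outcomes(tiles)
        assert cm.fn == 64 and cm.tp == 0

    def test_counts_conserved(self):
        rng = np.random.default_rng(0)
        tiles = []
        for _ in range(10 * 64):
            blank = rng.random() < 0.2
            tiles.append(
                _T(
                    "cancer" if rng.random() < 0.3 else "no_cancer",
                    blank=blank,
                    score=None if blank else float(rng.random()),
                )
            )
        cm = ev.tile_outcomes(tiles)
        assert cm.total == 640

    def test_missing_truth_rejected(self):
        with pytest.raises(DataError):
            ev.tile_outcomes([_T(None, blank=True)])

    def test_cutoff_is_inclusive(self):
        tiles = [_T("cancer", score=0.5), _T("cancer", score=0.499)]
        cm = ev.tile_outcomes(tiles)
        assert (cm.tp, cm.fn) == (1, 1)


class TestMatrixMetrics:
    def test_clinical_test_set_counts(self):
        # the group-B tile confusion matrix printed by the study
        cm = ev.ConfusionMatrix(tp=37267, fp=7815, fn=2283, tn=105787)
        accuracy, precision, recall, f = ev.matrix_metrics(cm)
        assert round(accuracy, 3) == 0.934
        assert round(precision, 3) == 0.827
        assert round(recall, 3) == 0.942
        assert round(f, 3) == 0.881

    def test_perfect_classifier(self):
        assert ev.matrix_metrics(ev.ConfusionMatrix(10, 0, 0, 10)) == (1.0, 1.0, 1.0, 1.0)

    def test_degenerate_no_positive_predictions(self):
        accuracy, precision, recall, f = ev.matrix_metrics(ev.ConfusionMatrix(0, 0, 5, 5))
        assert accuracy == 0.5
        assert recall == 0.0
        assert math.isnan(precision)
        assert math.isnan(f)


class TestMalignantProbability:
    def test_ratio_of_positive_tiles(self):
        tiles = [_T("no_cancer", score=0.9)] * 4 + [_T("no_cancer", score=0.1)] * 60
        assert ev.malignant_probability(tiles) == pytest.approx(0.0625)

    def test_extremes(self):
        assert ev.malignant_probability([_T("x", score=0.0)] * 64) == 0.0
        assert ev.malignant_probability([_T("x", score=1.0)] * 64) == 1.0

    def test_blanks_stay_in_denominator(self):
        tiles = [_T("x", score=0.9)] * 16 + [_T("x", blank=True)] * 48
        assert ev.malignant_probability(tiles) == pytest.approx(0.25)

    def test_wrong_tile_count_rejected(self):
        with pytest.raises(GeometryError):
            ev.malignant_probability([_T("x", score=1.0)] * 63)

    def test_four_of_64_meets_default_threshold(self):
        cfg = ev.VerdictConfig()
        assert cfg.is_malignant(4 / 64)
        assert not cfg.is_malignant(3 / 64)


class TestImageLevelRates:
    def test_clinical_operating_point(self):
        verdicts = _verdicts([1.0] * 1314 + [0.0] * 42, [0.0] * 974 + [1.0] * 63)
        for v in verdicts:
            v.predicted_class = "malignant" if v.malignant_probability >= 0.5 else "nonmalignant"
        sens, spec = ev.image_level_rates(verdicts)
        assert round(sens, 3) == 0.969
        assert round(spec, 3) == 0.939

    def test_all_correct(self):
        verdicts = _verdicts([1.0, 1.0], [0.0, 0.0])
        assert ev.image_level_rates(verdicts) == (1.0, 1.0)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(1)
        scores_c = rng.integers(0, 65, 40) / 64
        scores_n = rng.integers(0, 65, 40) / 64
        prev_sens, prev_spec = 1.0, 0.0
        for k in range(1, 64):
            thr = ev.VerdictConfig(threshold=k / 64)
            verdicts = _verdicts(scores_c, scores_n)
            for v in verdicts:
                v.predicted_class = (
                    "malignant" if thr.is_malignant(v.malignant_probability) else "nonmalignant"
                )
            sens, spec = ev.image_level_rates(verdicts)
            assert sens <= prev_sens + 1e-12
            assert spec >= prev_spec - 1e-12
            prev_sens, prev_spec = sens, spec


class TestRocCurve:
    def test_perfect_separation(self):
        _, auc = ev.roc_curve(_verdicts([0.8, 0.9], [0.1, 0.2]))
        assert auc == pytest.approx(1.0)

    def test_identical_scores_give_half(self):
        _, auc = ev.roc_curve(_verdicts([0.5, 0.5], [0.5, 0.5]))
        assert auc == pytest.approx(0.5)

    def test_one_swap_gives_three_quarters(self):
        # derived by brute-force pair counting
        pos, neg = [0.8, 0.4], [0.6, 0.2]
        assert pair_count_auc(pos, neg) == 0.75
        _, auc = ev.roc_curve(_verdicts(pos, neg))
        assert auc == pytest.approx(0.75)

    def test_trapezoid_equals_pair_counting(self):
        rng = np.random.default_rng(9)
        pos = rng.integers(0, 65, 30) / 64
        neg = rng.integers(0, 65, 25) / 64
        _, auc = ev.roc_curve(_verdicts(pos, neg))
        assert auc == pytest.approx(pair_count_auc(pos, neg), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(10)
        pos = rng.integers(0, 65, 50) / 64
        neg = rng.integers(0, 65, 50) / 64
        _, auc = ev.roc_curve(_verdicts(pos, neg))
        truth = [1] * 50 + [0] * 50
        assert auc == pytest.approx(roc_auc_score(truth, np.concatenate([pos, neg])))

    def test_single_class_undefined(self):
        _, auc = ev.roc_curve(_verdicts([0.5], []))
        assert math.isnan(auc)

    def test_endpoints(self):
        points, _ = ev.roc_curve(_verdicts([0.8], [0.2]))
        assert points[0] == (0.0, 0.0)
        assert points[-1] == (1.0, 1.0)


class TestMannWhitney:
    def test_type_one_error_rate(self):
        # identical distributions: rejection rate at alpha=.05 stays nominal
        rng = np.random.default_rng(123)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            g1 = rng.normal(0, 1, 50)
            g2 = rng.normal(0, 1, 50)
            _, p = ev.mann_whitney_u(g1, g2)
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_complete_separation(self):
        u, p = ev.mann_whitney_u([10, 11, 12], [1, 2, 3])
        assert u == 9  # n1 * n2
        assert p < 0.11  # smallest attainable two-sided exact p at 3/3

    def test_single_tied_pair(self):
        _, p = ev.mann_whitney_u([1.0], [1.0])
        assert p == 1.0

    def test_matches_scipy_on_large_samples(self):
        from scipy import stats

        rng = np.random.default_rng(5)
        g1 = rng.normal(0.3, 1, 80)
        g2 = rng.normal(0.0, 1, 70)
        u, p = ev.mann_whitney_u(g1, g2)
        ref = stats.mannwhitneyu(g1, g2, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidConfigError):
            ev.mann_whitney_u([], [1.0])


class TestCohensKappa:
    def test_perfect_agreement_table(self):
        # the pathologist-concordance table: 25 normal + 30 carcinoma, no
        # disagreements
        assert ev.cohens_kappa(ev.AgreementTable(((25, 0), (0, 30)))) == pytest.approx(1.0)

    def test_one_constant_rater_gives_zero(self):
        assert ev.cohens_kappa(ev.AgreementTable(((6, 4), (0, 0)))) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # p_o = 35/50, p_e = (30*25 + 20*25)/2500 = 0.5 -> kappa 0.4
        assert ev.cohens_kappa(ev.AgreementTable(((20, 5), (10, 15)))) == pytest.approx(0.4)

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        table = ((18, 7), (4, 21))
        r1 = [0] * 25 + [1] * 25
        r2 = [0] * 18 + [1] * 7 + [0] * 4 + [1] * 21
        assert ev.cohens_kappa(ev.AgreementTable(table)) == pytest.approx(
            cohen_kappa_score(r1, r2)
        )

    def test_empty_table_rejected(self):
        with pytest.raises(InvalidConfigError):
            ev.AgreementTable(((0, 0), (0, 0)))
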