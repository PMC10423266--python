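import itertools
import logging

import numpy as np
import pytest
from scipy import stats

from petmip.evaluation import (apply_calibration, classify_at_cutoff,
                               delong_test, feature_association,
                               fit_calibration, ipi_baseline, roc_auc)
from petmip.volume_io import PatientRecord, TTP0, TTP1


def pairwise_auc(scores, labels):
    """All-pairs oracle: wins + half-ties over positive/negative pairs."""
    scores, labels = np.asarray(scores), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_worked_example(self):
        scores = [0.35, 0.8, 0.1, 0.4]
        labels = [1, 1, 0, 0]
        assert roc_auc(scores, labels) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_is_half(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            roc_auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 21))
        scores = np.round(rng.random(n), 1)          # rounding creates ties
        labels = np.r_[1, 0, (rng.random(n - 2) < 0.5).astype(int)]
        assert roc_auc(scores, labels) == pytest.approx(pairwise_auc(scores, labels))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.random(30)
        labels = np.r_[np.ones(10, int), np.zeros(20, int)]
        a0 = roc_auc(scores, labels)
        for f in (np.exp, lambda s: 3 * s - 7, lambda s: s**3):
            assert roc_auc(f(scores), labels) == pytest.approx(a0)


class TestClassifyAtCutoff:
    def test_perfect_split(self):
        rep = classify_at_cutoff([0.7, 0.6, 0.4, 0.3], [1, 1, 0, 0])
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0
        assert rep.n_pos == 2 and rep.n_neg == 2

    def test_exact_cutoff_counts_positive(self):
        rep = classify_at_cutoff([0.5], [1])
        assert rep.sensitivity == 1.0

    def test_label_flip_swaps_sensitivity_specificity(self):
        p = [0.9, 0.6, 0.2, 0.4, 0.1]
        y = [1, 0, 0, 1, 0]
        a = classify_at_cutoff(p, y)
        b = classify_at_cutoff([1 - x for x in p], [1 - l for l in y])
        assert a.sensitivity == pytest.approx(b.specificity)
        assert a.specificity == pytest.approx(b.sensitivity)

    def test_no_positives_gives_nan_sensitivity(self):
        rep = classify_at_cutoff([0.2, 0.3], [0, 0])
        assert np.isnan(rep.sensitivity)
        assert rep.specificity == 1.0

    def test_cutoff_sweep_reproduces_roc_steps(self):
        rng = np.random.default_rng(1)
        p = rng.random(40)
        y = (rng.random(40) < 0.4).astype(int)
        pts = {(classify_at_cutoff(p, y, cutoff=c).sensitivity,
                classify_at_cutoff(p, y, cutoff=c).specificity)
               for c in np.r_[0, np.sort(p), 1.0001]}
        # trapezoid over the swept (FPR, TPR) points equals the rank AUC
        curve = sorted((1 - sp, se) for se, sp in pts)
        auc = np.trapezoid([t for _, t in curve], [f for f, _ in curve])
        assert auc == pytest.approx(roc_auc(p, y), abs=1e-9)


class TestDeLong:
    def test_identical_scores_degenerate(self):
        res = delong_test([0.1, 0.9, 0.4], [0.1, 0.9, 0.4], [0, 1, 1])
        assert res.degenerate and res.p_value == 1.0
        assert res.auc_a == res.auc_b

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(5)
        y = np.r_[np.ones(8, int), np.zeros(10, int)]
        a, b = rng.random(18), rng.random(18)
        r1 = delong_test(a, b, y)
        r2 = delong_test(b, a, y)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.z == pytest.approx(-r2.z)

    def test_aucs_match_rank_formulation(self):
        rng = np.random.default_rng(8)
        y = np.r_[np.ones(6, int), np.zeros(9, int)]
        a, b = rng.random(15), rng.random(15)
        res = delong_test(a, b, y)
        assert res.auc_a == pytest.approx(roc_auc(a, y))
        assert res.auc_b == pytest.approx(roc_auc(b, y))

    def test_matches_exhaustive_permutation_oracle(self):
        """Asymptotic DeLong p vs the exact paired sign-swap permutation
        distribution of the AUC difference at n=12.

        The permutation distribution is discrete, so the mid-p convention
        (half-weight to ties) is compared; at n=12 the normal approximation
        tracks it to ~0.1, with occasional deviations up to ~0.15.
        """
        rng = np.random.default_rng(4)
        n = 12
        y = np.r_[np.ones(6, int), np.zeros(6, int)]
        diffs = []
        for _ in range(6):
            a = np.clip(y * 0.35 + rng.random(n) * 0.6, 0, 1)
            b = rng.random(n)
            obs = abs(roc_auc(a, y) - roc_auc(b, y))
            gt = eq = 0
            for swap in itertools.product([0, 1], repeat=n):
                sa = np.where(swap, b, a)
                sb = np.where(swap, a, b)
                d = abs(roc_auc(sa, y) - roc_auc(sb, y))
                if d > obs + 1e-12:
                    gt += 1
                elif d >= obs - 1e-12:
                    eq += 1
            p_mid = (gt + 0.5 * eq) / 2**n
            diffs.append(abs(delong_test(a, b, y).p_value - p_mid))
        assert max(diffs) < 0.15
        assert np.mean(diffs) < 0.08

    def test_null_p_values_uniform(self):
        """Under a global null (two independent noise scores) the DeLong
        p-values are approximately uniform (KS check, alpha = 0.01)."""
        rng = np.random.default_rng(12)
        pvals = []
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        for _ in range(500):
            a, b = rng.normal(size=40), rng.normal(size=40)
            pvals.append(delong_test(a, b, y).p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            delong_test([0.1, 0.2], [0.1], [0, 1])


class TestIPIBaseline:
    def records(self, scores):
        return [PatientRecord(f"p{i}", TTP1 if i % 2 else TTP0, ipi_score=s)
                for i, s in enumerate(scores)]

    def test_four_or_higher_is_high_risk(self):
        table = ipi_baseline(self.records([4, 3, 5, 0]))
        assert table.high_risk.tolist() == [True, False, True, False]

    def test_missing_ipi_lists_patients(self):
        recs = self.records([4, 3]) + [PatientRecord("px", TTP0)]
        with pytest.raises(ValueError, match="px"):
            ipi_baseline(recs)

    def test_auc_composable_with_roc(self):
        table = ipi_baseline(self.records([0, 5, 1, 4, 2, 3]))
        auc = roc_auc(table.ipi_score, table.label)
        assert 0 <= auc <= 1


class TestCalibration:
    def test_slope_positive_for_informative_probabilities(self):
        rng = np.random.default_rng(2)
        p = rng.random(300)
        y = (rng.random(300) < 0.2 + 0.6 * p).astype(int)
        fit = fit_calibration(p, y)
        assert fit.slope > 0

    def test_auc_preserved_by_monotone_calibration(self):
        rng = np.random.default_rng(9)
        p = rng.random(100)
        y = (rng.random(100) < p).astype(int)
        fit = fit_calibration(p, y)
        assert fit.slope > 0
        assert roc_auc(apply_calibration(fit, p), y) == pytest.approx(roc_auc(p, y))

    def test_outputs_strictly_inside_unit_interval(self):
        fit = fit_calibration([0.1, 0.9, 0.2, 0.8], [0, 1, 1, 0])
        out = apply_calibration(fit, np.array([0.0, 0.5, 1.0]))
        assert ((out > 0) & (out < 1)).all()

    def test_coefficient_recovery_on_simulated_logits(self):
        rng = np.random.default_rng(0)
        a, b = -2.0, 4.0
        p = rng.random(2000)
        y = (rng.random(2000) < 1 / (1 + np.exp(-(a + b * p)))).astype(int)
        fit = fit_calibration(p, y)
        assert fit.intercept == pytest.approx(a, abs=0.5)
        assert fit.slope == pytest.approx(b, abs=0.8)

    def test_perfect_separation_falls_back_penalized(self, caplog):
        p = np.r_[np.zeros(10), np.ones(10)]
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        with caplog.at_level(logging.WARNING, logger="petmip.evaluation"):
            fit = fit_calibration(p, y)
        assert fit.penalized
        assert fit.slope > 0


class TestFeatureAssociation:
    def test_linear_feature_gives_r_one(self):
        p = np.array([0.1, 0.2, 0.4, 0.5])
        r, _ = feature_association(p, {"mtv": 10 * p + 3})
        assert r["mtv"] == pytest.approx(1.0)

    def test_hand_computed_five_points(self):
        p = np.array([1.0, 2, 3, 4, 5])
        f = np.array([2.0, 1, 4, 3, 6])
        cov = np.mean((p - p.mean()) * (f - f.mean()))
        expected = cov / (p.std() * f.std())
        r, scatter = feature_association(p, {"f": f})
        assert r["f"] == pytest.approx(expected)
        assert list(scatter.columns) == ["p_ttp1", "f"]

    def test_permuted_feature_has_small_r(self):
        rng = np.random.default_rng(6)
        p = rng.random(1000)
        r, _ = feature_association(p, {"noise": rng.permutation(p)})
        assert abs(r["noise"]) < 0.1

    def test_zero_variance_feature_is_nan(self):
        r, _ = feature_association([0.2, 0.5, 0.7], {"flat": [1.0, 1.0, 1.0]})
        assert np.isnan(r["flat"])

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            feature_association([0.1, 0.2], {"x": [1, 2]})
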