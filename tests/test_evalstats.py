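"""Metrics and statistics: overlap identities, ROC equivalences against
brute-force and library oracles, the responder rule, and the test
battery against independent implementations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sinusvol.evalstats import (
    confusion_matrix,
    region_agreement,
    responder,
    roc,
    seg_metrics,
    stat_battery,
)
from sinusvol.regions import REGION_IDS
from sinusvol.volumetrics import RegionReport


class TestSegMetrics:
    def test_identical_maps_are_perfect(self):
        a = np.random.default_rng(0).integers(0, 5, (10, 10))
        m = seg_metrics(a, a)
        assert m.pixel_accuracy == 1.0
        assert m.mean_dice == 1.0 and m.miou == 1.0

    def test_disjoint_binary_masks(self):
        pred = np.array([[1, 1, 0, 0]])
        ref = np.array([[0, 0, 1, 1]])
        m = seg_metrics(pred, ref)
        assert m.per_class_dice[1] == 0.0 and m.per_class_iou[1] == 0.0

    def test_half_overlap_worked_example(self):
        """Two 2-pixel masks overlapping in 1 pixel: Dice 1/2, IoU 1/3."""
        pred = np.array([[1, 1, 0], [0, 0, 0]])
        ref = np.array([[0, 1, 1], [0, 0, 0]])
        m = seg_metrics(pred, ref)
        assert m.per_class_dice[1] == pytest.approx(0.5)
        assert m.per_class_iou[1] == pytest.approx(1.0 / 3.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            seg_metrics(np.zeros((2, 2), int), np.zeros((2, 3), int))

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_dice_iou_identity_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.integers(0, 4, (12, 12))
        ref = rng.integers(0, 4, (12, 12))
        m = seg_metrics(pred, ref)
        for c, d in m.per_class_dice.items():
            assert m.per_class_iou[c] == pytest.approx(d / (2.0 - d), abs=1e-12)
        if m.per_class_dice:
            vals = list(m.per_class_dice.values())
            assert min(vals) - 1e-12 <= m.mean_dice <= max(vals) + 1e-12

    def test_matches_confusion_matrix_trace(self):
        rng = np.random.default_rng(1)
        pred = rng.integers(0, 3, (8, 8))
        ref = rng.integers(0, 3, (8, 8))
        cm = confusion_matrix(pred, ref)
        assert seg_metrics(pred, ref).pixel_accuracy \
            == pytest.approx(np.trace(cm) / cm.sum())


def _reports(ratios):
    return [RegionReport.from_counts(rid, int(100 * (1 - r)), int(100 * r), 0.001)
            for rid, r in zip(REGION_IDS, ratios)]


class TestRegionAgreement:
    def test_perfect_agreement(self):
        ref = {f"s{i}": _reports([0.3] * 12) for i in range(5)}
        table = region_agreement(ref, ref)
        assert (table.to_numpy() == 1.0).all()
        assert list(table.columns) == ["Left", "Right"]

    def test_one_discordant_subject_of_twenty(self):
        ref = {f"s{i}": _reports([0.3] * 12) for i in range(20)}
        pred = {k: v for k, v in ref.items()}
        bad = _reports([0.9] + [0.3] * 11)  # Max-L off by 0.6
        pred["s0"] = bad
        table = region_agreement(pred, ref, tolerance=0.1)
        assert table.loc["Max", "Left"] == pytest.approx(0.95)
        assert table.loc["Max", "Right"] == 1.0

    def test_injected_error_rate_recovered(self):
        rng = np.random.default_rng(4)
        eps = 0.2
        n = 200
        ref, pred = {}, {}
        flips = 0
        for i in range(n):
            ref[f"s{i}"] = _reports([0.3] * 12)
            if rng.random() < eps:
                pred[f"s{i}"] = _reports([0.8] + [0.3] * 11)
                flips += 1
            else:
                pred[f"s{i}"] = _reports([0.3] * 12)
        table = region_agreement(pred, ref, tolerance=0.1)
        assert table.loc["Max", "Left"] == pytest.approx(1 - flips / n)

    def test_unmatched_ids_rejected(self):
        with pytest.raises(ValueError, match="subject ids"):
            region_agreement({"a": _reports([0] * 12)},
                             {"b": _reports([0] * 12)})


class TestRoc:
    def test_perfect_separation(self):
        r = roc([1, 2, 3, 4], [0, 0, 1, 1])
        assert r.auc == 1.0
        assert r.youden_cutpoint == pytest.approx(2.5)
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_pure_ties(self):
        assert roc([5, 5, 5, 5], [0, 1, 0, 1]).auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc([1, 2, 3], [1, 1, 1])

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(4, 40))
    def test_trapezoid_auc_equals_rank_statistic(self, seed, n):
        """AUC from the curve equals brute-force pair counting
        P(s+ > s-) + 0.5 P(tie), exactly."""
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 8, n).astype(float)  # many ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        r = roc(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert r.auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        scores = rng.normal(size=60) + rng.integers(0, 2, 60)
        labels = rng.integers(0, 2, 60)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert roc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        labels[0], labels[1] = 0, 1
        a1 = roc(scores, labels).auc
        a2 = roc(np.exp(2.0 * scores) + 5, labels).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_curve_monotone(self):
        rng = np.random.default_rng(9)
        r = roc(rng.normal(size=50), rng.integers(0, 2, 50)
                if True else None)
        assert np.all(np.diff(r.fpr) >= 0)
        assert np.all(np.diff(r.tpr) >= 0)


class TestResponder:
    def test_exact_quarter_reduction_is_responder(self):
        assert responder(40, 30) is True

    def test_smaller_reduction_is_not(self):
        assert responder(40, 31) is False

    def test_nonpositive_pre_rejected(self):
        with pytest.raises(ValueError):
            responder(0, 0)

    def test_cohort_responder_fraction_near_configured(self):
        from sinusvol.phantom import generate_cohort

        recs = [r for r, _ in generate_cohort(400, seed=19)]
        surg = [r for r in recs if r.surgery]
        frac = np.mean([responder(r.snot22_pre, r.snot22_post) for r in surg])
        # binomial slack around the configured 0.6
        assert abs(frac - 0.6) < 3 * np.sqrt(0.6 * 0.4 / len(surg)) + 0.05


class TestStatBattery:
    def test_identical_groups_null(self):
        df = pd.DataFrame({"v": [1.0, 2, 3, 4] * 2,
                           "g": ["a"] * 4 + ["b"] * 4})
        res = stat_battery(df, [{"kind": "ttest", "value": "v", "group": "g"}])
        assert res.statistic.iloc[0] == pytest.approx(0.0)
        assert res.p_value.iloc[0] == pytest.approx(1.0)
        assert not res.significant.iloc[0]

    def test_exact_recovery_on_noise_free_regression(self):
        rng = np.random.default_rng(5)
        x1 = rng.normal(size=50)
        x2 = rng.normal(size=50)
        df = pd.DataFrame({"x1": x1, "x2": x2, "y": 2.0 + 3.0 * x1 - 0.5 * x2})
        res = stat_battery(df, [{"kind": "ols", "formula": "y ~ x1 + x2"}])
        est = dict(zip(res.term, res.estimate))
        assert est["x1"] == pytest.approx(3.0, abs=1e-10)
        assert est["x2"] == pytest.approx(-0.5, abs=1e-10)

    def test_matches_independent_implementations(self):
        """t/ANOVA/OLS agree with pingouin and numpy lstsq to 1e-8."""
        import pingouin as pg

        rng = np.random.default_rng(6)
        df = pd.DataFrame({
            "v": rng.normal(size=60),
            "g": np.repeat(["a", "b", "c"], 20),
            "x": rng.normal(size=60),
        })
        two = df[df.g != "c"]
        res = stat_battery(two, [{"kind": "ttest", "value": "v", "group": "g"}])
        ref = pg.ttest(two[two.g == "a"].v, two[two.g == "b"].v, correction=True)
        assert res.statistic.iloc[0] == pytest.approx(float(ref["T"].iloc[0]),
                                                      abs=1e-8)
        assert res.p_value.iloc[0] == pytest.approx(float(ref["p_val"].iloc[0]),
                                                    abs=1e-8)
        resa = stat_battery(df, [{"kind": "anova", "value": "v", "group": "g"}])
        refa = pg.anova(data=df, dv="v", between="g")
        assert resa.statistic.iloc[0] == pytest.approx(float(refa["F"].iloc[0]),
                                                       abs=1e-8)
        reso = stat_battery(df, [{"kind": "ols", "formula": "v ~ x"}])
        beta = np.linalg.lstsq(np.c_[np.ones(60), df.x], df.v, rcond=None)[0]
        assert dict(zip(reso.term, reso.estimate))["x"] == pytest.approx(
            beta[1], abs=1e-8)

    def test_degenerate_groups_rejected(self):
        df = pd.DataFrame({"v": [1.0, 2, 3], "g": ["a", "a", "b"]})
        with pytest.raises(ValueError, match="degenerate"):
            stat_battery(df, [{"kind": "ttest", "value": "v", "group": "g"}])
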