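"""Metric-formula oracles, bootstrap behaviour and the statistical tests."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mlnet.evalstats import (
    ConfusionCounts,
    auc_rank,
    bootstrap_ci,
    clinical_lr,
    confusion_counts,
    confusion_metrics,
    dice,
    kruskal_wallis,
    mann_whitney,
    metric_report,
    roc_curve,
    youden_threshold,
)


# ---------------------------------------------------------------------- dice


def brute_dice(a, b):
    """Independent set-overlap oracle."""
    sa = {tuple(i) for i in np.argwhere(a)}
    sb = {tuple(i) for i in np.argwhere(b)}
    if not sa and not sb:
        return 1.0
    return 2 * len(sa & sb) / (len(sa) + len(sb))


class TestDice:
    def test_identity(self):
        m = np.zeros((4, 4, 4), np.uint8)
        m[1:3, 1:3, 1:3] = 1
        assert dice(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4, 4), np.uint8)
        b = np.zeros((4, 4, 4), np.uint8)
        a[0, 0, 0] = 1
        b[3, 3, 3] = 1
        assert dice(a, b) == 0.0

    def test_worked_example(self):
        # pred = {v1,v2,v3}, gt = {v2,v3,v4,v5} -> 2*2/(2*2+1+2) = 4/7
        a = np.zeros((2, 2, 2), np.uint8)
        b = np.zeros((2, 2, 2), np.uint8)
        a.flat[[0, 1, 2]] = 1
        b.flat[[1, 2, 3, 4]] = 1
        assert dice(a, b) == pytest.approx(4 / 7)

    def test_both_empty_convention(self):
        z = np.zeros((3, 3, 3), np.uint8)
        assert dice(z, z) == 1.0
        g = z.copy()
        g[1, 1, 1] = 1
        assert dice(z, g) == 0.0

    def test_grid_mismatch(self):
        with pytest.raises(ValueError, match="grid"):
            dice(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))

    def test_against_set_oracle_100_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a = (rng.random((5, 5, 5)) > rng.uniform(0.2, 0.9)).astype(np.uint8)
            b = (rng.random((5, 5, 5)) > rng.uniform(0.2, 0.9)).astype(np.uint8)
            assert dice(a, b) == pytest.approx(brute_dice(a, b))


# ----------------------------------------------------------------------- auc


def brute_auc(scores, labels):
    """Exhaustive pairwise-comparison oracle: P(pos > neg) + 0.5 P(tie)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestAucRank:
    def test_perfect(self):
        assert auc_rank([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert auc_rank([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_worked_example(self):
        # 3 of 4 pairs correctly ordered
        assert auc_rank([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc_rank([0.1, 0.2], [1, 1])

    def test_matches_pairwise_oracle_all_n(self):
        rng = np.random.default_rng(1)
        for n in range(2, 31):
            for rep in range(8):
                labels = np.zeros(n, int)
                labels[: rng.integers(1, n)] = 1
                rng.shuffle(labels)
                if labels.sum() in (0, n):
                    continue
                scores = rng.choice([0.1, 0.25, 0.5, 0.7, 0.9], size=n)
                assert auc_rank(scores, labels) == pytest.approx(
                    brute_auc(scores, labels)
                )

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 9), st.booleans()), min_size=4, max_size=25))
    def test_property_matches_oracle(self, pairs):
        scores = np.array([p[0] / 10 for p in pairs])
        labels = np.array([int(p[1]) for p in pairs])
        if labels.sum() in (0, len(labels)):
            return
        assert auc_rank(scores, labels) == pytest.approx(brute_auc(scores, labels))


# ----------------------------------------------------------- confusion table


class TestConfusionMetrics:
    def test_worked_example(self):
        # TP=3, FP=1, FN=2, TN=4
        scores = np.r_[np.full(3, 0.9), np.full(1, 0.9), np.full(2, 0.1), np.full(4, 0.1)]
        labels = np.r_[np.ones(3), np.zeros(1), np.ones(2), np.zeros(4)].astype(int)
        m = confusion_metrics(scores, labels, threshold=0.5)
        assert m.counts == ConfusionCounts(tp=3, fp=1, fn=2, tn=4)
        assert m.sensitivity == pytest.approx(0.6)
        assert m.specificity == pytest.approx(0.8)
        assert m.ppv == pytest.approx(0.75)
        assert m.npv == pytest.approx(2 / 3)
        assert m.f1 == pytest.approx(3 / 4.5)

    def test_threshold_below_min(self):
        m = confusion_metrics([0.2, 0.5, 0.7], [1, 0, 1], threshold=0.0)
        assert m.sensitivity == 1.0
        assert m.specificity == 0.0

    def test_zero_denominator_is_nan_with_warning(self):
        with pytest.warns(RuntimeWarning, match="NPV"):
            m = confusion_metrics([0.9, 0.8], [1, 0], threshold=0.5)
        assert np.isnan(m.npv)

    def test_brute_force_50_cases(self):
        rng = np.random.default_rng(3)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        thr = 0.4
        m = confusion_metrics(scores, labels, threshold=thr, warn=False)
        tp = sum(1 for s, y in zip(scores, labels) if s >= thr and y == 1)
        fp = sum(1 for s, y in zip(scores, labels) if s >= thr and y == 0)
        fn = sum(1 for s, y in zip(scores, labels) if s < thr and y == 1)
        tn = sum(1 for s, y in zip(scores, labels) if s < thr and y == 0)
        assert m.counts == ConfusionCounts(tp, fp, fn, tn)
        assert m.sensitivity == pytest.approx(tp / (tp + fn))
        assert m.f1 == pytest.approx(tp / (tp + 0.5 * (fp + fn)))

    def test_count_consistency_invariant(self):
        rng = np.random.default_rng(4)
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        m = confusion_metrics(scores, labels, threshold=0.5, warn=False)
        c = m.counts
        assert m.sensitivity * (c.tp + c.fn) == pytest.approx(round(m.sensitivity * (c.tp + c.fn)))
        assert m.specificity * (c.tn + c.fp) == pytest.approx(round(m.specificity * (c.tn + c.fp)))


# --------------------------------------------------------------- youden / roc


class TestYouden:
    def test_perfect_separation(self):
        op = youden_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert op.youden_j == pytest.approx(1.0)

    def test_tie_break_smallest_threshold(self):
        op = youden_threshold([0.2, 0.3, 0.6, 0.8], [0, 1, 0, 1])
        assert op.youden_j == pytest.approx(0.5)
        assert op.threshold == pytest.approx(0.3)

    def test_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(5)
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        op = youden_threshold(scores, labels)
        js = []
        for thr in np.unique(scores):
            m = confusion_metrics(scores, labels, threshold=thr, warn=False)
            js.append(m.sensitivity + m.specificity - 1)
        assert op.youden_j == pytest.approx(max(js))

    def test_null_j_small(self):
        rng = np.random.default_rng(6)
        scores = rng.random(2000)
        labels = rng.integers(0, 2, 2000)
        op = youden_threshold(scores, labels)
        assert op.youden_j <= 0.15

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            youden_threshold([0.1, 0.9], [1, 1])


class TestRoc:
    def test_perfect_passes_through_corner(self):
        fpr, tpr = roc_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert any(f == 0.0 and t == 1.0 for f, t in zip(fpr, tpr))

    def test_endpoints_and_monotone(self):
        rng = np.random.default_rng(7)
        fpr, tpr = roc_curve(rng.random(50), rng.integers(0, 2, 50))
        assert (fpr[0], tpr[0]) == (0.0, 0.0)
        assert (fpr[-1], tpr[-1]) == (1.0, 1.0)
        assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()

    def test_area_equals_auc_rank_100_sets(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = rng.integers(5, 60)
            scores = rng.choice(np.linspace(0, 1, 11), size=n)
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            fpr, tpr = roc_curve(scores, labels)
            area = np.trapezoid(tpr, fpr)
            assert area == pytest.approx(auc_rank(scores, labels), abs=1e-9)

    def test_reversed_scores_mirror(self):
        rng = np.random.default_rng(9)
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        a = auc_rank(scores, labels)
        b = auc_rank(1 - scores, labels)
        assert a + b == pytest.approx(1.0)


# ------------------------------------------------------------------ bootstrap


class TestBootstrap:
    def test_degenerate_perfect_auc(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        labels = [0, 0, 1, 1]
        lo, hi = bootstrap_ci(auc_rank, scores, labels, n_boot=200, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(10)
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        a = bootstrap_ci(auc_rank, scores, labels, n_boot=500, seed=3)
        b = bootstrap_ci(auc_rank, scores, labels, n_boot=500, seed=3)
        assert a == b

    def test_interval_shrinks_with_n(self):
        rng = np.random.default_rng(11)
        widths = {}
        for n in (50, 400):
            ws = []
            for rep in range(50):
                labels = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
                scores = np.clip(rng.normal(0.5 + 0.2 * labels, 0.2), 0, 1)
                lo, hi = bootstrap_ci(auc_rank, scores, labels, n_boot=200, seed=rep)
                ws.append(hi - lo)
            widths[n] = np.mean(ws)
        assert widths[400] < widths[50]

    def test_metric_report_structure(self):
        rng = np.random.default_rng(12)
        labels = rng.integers(0, 2, 60)
        scores = np.clip(rng.normal(0.4 + 0.3 * labels, 0.2), 0, 1)
        rep = metric_report(scores, labels, n_boot=200, seed=0)
        for name in ("auc", "sensitivity", "specificity", "ppv", "npv", "f1"):
            point, lo, hi = rep.metrics[name]
            assert 0.0 <= point <= 1.0
            assert lo <= point + 1e-9 and point - 1e-9 <= hi


# ----------------------------------------------------------- rank-based tests


class TestKruskalWallis:
    def test_identical_groups(self):
        h, p = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_ranked_example(self):
        # groups (1,2,3) vs (4,5,6): ranks 1..6, R1=6, R2=15
        # H = 12/(6*7) * (36/3 + 225/3) - 3*7 = 12/42*87 - 21 = 27/7
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(27 / 7)
        from scipy.stats import chi2

        assert p == pytest.approx(chi2.sf(27 / 7, 1))

    def test_power_on_shifted_distributions(self):
        rng = np.random.default_rng(13)
        x = rng.normal(0, 1, 200)
        y = rng.normal(0.5, 1, 200)
        _, p = kruskal_wallis([x, y])
        assert p < 0.05

    def test_too_few_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


class TestMannWhitney:
    def test_identical_samples(self):
        _, p = mann_whitney(np.arange(30.0), np.arange(30.0))
        assert p > 0.9

    def test_exact_worked_example(self):
        # x=(1,2), y=(3,4): U=0; of the C(4,2)=6 label arrangements two give
        # U <= 0 or U >= 4, so two-sided p = 2/6 = 1/3
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_enumeration_oracle(self):
        x = np.array([1.0, 2.0])
        y = np.array([3.0, 4.0])
        pooled = np.r_[x, y]
        count = 0
        total = 0
        observed_u = 0.0
        for combo in itertools.combinations(range(4), 2):
            xs = pooled[list(combo)]
            ys = pooled[[i for i in range(4) if i not in combo]]
            u = sum(1.0 for a in xs for b in ys if a > b)
            total += 1
            if min(u, 4 - u) <= min(observed_u, 4 - observed_u):
                count += 1
        assert count / total == pytest.approx(1 / 3)

    def test_u_identity(self):
        rng = np.random.default_rng(14)
        x = rng.random(15)
        y = rng.random(9)
        u1, _ = mann_whitney(x, y)
        u2, _ = mann_whitney(y, x)
        assert u1 + u2 == pytest.approx(len(x) * len(y))

    def test_empty_sample(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


# --------------------------------------------------------------- clinical LR


def _make_table(rng, n, beta_ct=0.0, target="emvi"):
    import pandas as pd

    age = rng.normal(64, 10, n)
    sex = rng.choice(["F", "M"], n)
    ct = rng.choice(["1-2", "3", "4"], n, p=[0.2, 0.6, 0.2])
    cn = rng.choice([0, 1, 2], n)
    eta = -0.3 + beta_ct * (ct == "4") + beta_ct * 0.5 * (ct == "3")
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "age": age,
            "sex": sex,
            "cT": ct,
            "cN": cn,
            target: y,
            "cr" if target == "emvi" else "emvi": 0,
        }
    )


class TestClinicalLR:
    def test_null_covariate_ci_covers_zero(self):
        rng = np.random.default_rng(15)
        df = _make_table(rng, 500, beta_ct=0.0)
        _, model = clinical_lr(df, target="emvi")
        lo, hi = model.conf_int.loc["age"]
        assert lo <= 0.0 <= hi

    def test_intercept_only_prevalence(self):
        rng = np.random.default_rng(16)
        df = _make_table(rng, 300, beta_ct=0.0)
        scores, _ = clinical_lr(df, covariates=(), target="emvi")
        assert np.allclose(scores.scores, df["emvi"].mean(), atol=1e-6)

    def test_recovers_planted_ct_effect(self):
        rng = np.random.default_rng(17)
        dev = _make_table(rng, 600, beta_ct=2.5)
        ext = _make_table(rng, 300, beta_ct=2.5)
        scores, _ = clinical_lr(dev, ext, target="emvi")
        assert auc_rank(scores) > 0.7

    def test_single_class_target_rejected(self):
        rng = np.random.default_rng(18)
        df = _make_table(rng, 50)
        df["emvi"] = 1
        with pytest.raises(ValueError):
            clinical_lr(df, target="emvi")
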