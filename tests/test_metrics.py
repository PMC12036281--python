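"""Dice, weighted score metrics, bootstrap CIs, paired-report evaluation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sinuslms.errors import ShapeMismatchError
from sinuslms.metrics import (
    MetricSummary,
    ScoreConfusion,
    bootstrap_ci,
    dice,
    dice_table,
    evaluate_lms,
    score_metrics,
)
from sinuslms.regions import Region
from sinuslms.scoring import LMSReport, RegionScore


def _report(scores: dict) -> LMSReport:
    out = {}
    for region in Region:
        s = scores.get(region, 0)
        out[region] = RegionScore(region, s, False, 100, 0, 0.0, -300.0)
    return LMSReport(out)


class TestDice:
    def test_self_overlap_is_one(self):
        m = np.zeros((8, 8), bool)
        m[2:5, 2:5] = True
        assert dice(m, m) == 1.0

    def test_disjoint_masks_are_zero(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[:2], b[6:] = True, True
        assert dice(a, b) == 0.0

    def test_hand_computed_example(self):
        # |A|=4, |B|=6, |A∩B|=3 -> 2*3/(4+6) = 0.6
        a = np.zeros(10, bool)
        b = np.zeros(10, bool)
        a[:4] = True
        b[1:7] = True
        assert dice(a, b) == pytest.approx(0.6)

    def test_empty_mask_conventions(self):
        e = np.zeros((4, 4), bool)
        f = np.zeros((4, 4), bool)
        f[0, 0] = True
        assert dice(e, e) == 1.0
        assert dice(e, f) == 0.0 and dice(f, e) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeMismatchError):
            dice(np.zeros((2, 2), bool), np.zeros((3, 3), bool))

    @given(st.integers(0, 10_000))
    def test_symmetry_and_range_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((12, 12)) < 0.3
        b = rng.random((12, 12)) < 0.3
        d = dice(a, b)
        assert d == dice(b, a)
        assert 0.0 <= d <= 1.0

    def test_equivalence_with_pixel_loop_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            shape = tuple(rng.integers(2, 64, size=2))
            a = rng.random(shape) < rng.uniform(0.05, 0.6)
            b = rng.random(shape) < rng.uniform(0.05, 0.6)
            na = nb = ninter = 0
            for i in range(shape[0]):
                for j in range(shape[1]):
                    na += int(a[i, j])
                    nb += int(b[i, j])
                    ninter += int(a[i, j] and b[i, j])
            expected = 1.0 if na + nb == 0 else 2 * ninter / (na + nb)
            assert dice(a, b) == pytest.approx(expected)


def _brute_force_metrics(counts):
    """Independent per-class precision/recall/F1 loop, weighted by support."""
    counts = np.asarray(counts, float)
    total = counts.sum()
    acc = np.trace(counts) / total
    wp = wr = wf = 0.0
    for c in range(3):
        support = counts[c].sum()
        if support == 0:
            continue
        pred = counts[:, c].sum()
        prec = counts[c, c] / pred if pred > 0 else 0.0
        rec = counts[c, c] / support
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        w = support / total
        wp += w * prec
        wr += w * rec
        wf += w * f1
    return acc, wp, wr, wf


class TestScoreMetrics:
    def test_perfect_predictor(self):
        m = score_metrics(ScoreConfusion(np.diag([4, 5, 6])))
        assert m.accuracy == m.weighted_precision == m.weighted_recall == m.weighted_f1 == 1.0

    def test_single_class_truth(self):
        m = score_metrics(ScoreConfusion([[5, 0, 0], [0, 0, 0], [0, 0, 0]]))
        assert m.accuracy == 1.0
        assert m.weighted_f1 == 1.0

    def test_hand_example_matches_brute_force(self):
        counts = [[8, 2, 0], [1, 6, 1], [0, 1, 5]]
        m = score_metrics(ScoreConfusion(counts))
        acc, wp, wr, wf = _brute_force_metrics(counts)
        assert m.accuracy == pytest.approx(acc, abs=1e-15)
        assert m.weighted_precision == pytest.approx(wp, abs=1e-15)
        assert m.weighted_recall == pytest.approx(wr, abs=1e-15)
        assert m.weighted_f1 == pytest.approx(wf, abs=1e-15)

    def test_matches_sklearn_weighted_metrics(self):
        from sklearn.metrics import precision_recall_fscore_support

        rng = np.random.default_rng(0)
        counts = rng.integers(0, 9, size=(3, 3))
        counts[0, 0] += 1  # ensure nonzero
        y_true, y_pred = [], []
        for t in range(3):
            for p in range(3):
                y_true += [t] * counts[t, p]
                y_pred += [p] * counts[t, p]
        m = score_metrics(ScoreConfusion(counts))
        prec, rec, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, average="weighted", zero_division=0
        )
        assert m.weighted_precision == pytest.approx(prec, abs=1e-12)
        assert m.weighted_recall == pytest.approx(rec, abs=1e-12)
        assert m.weighted_f1 == pytest.approx(f1, abs=1e-12)

    @given(st.integers(0, 10_000))
    def test_weighted_recall_equals_accuracy(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 20, size=(3, 3))
        if counts.sum() == 0:
            counts[1, 1] = 1
        m = score_metrics(ScoreConfusion(counts))
        assert m.weighted_recall == pytest.approx(m.accuracy, abs=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            score_metrics(ScoreConfusion(np.zeros((3, 3), int)))


class TestBootstrap:
    def test_constant_values_collapse(self):
        lo, hi = bootstrap_ci([0.7] * 10, seed=1)
        assert lo == hi == pytest.approx(0.7)

    def test_seeded_determinism(self):
        vals = np.random.default_rng(2).random(20)
        assert bootstrap_ci(vals, seed=9) == bootstrap_ci(vals, seed=9)
        assert bootstrap_ci(vals, seed=9) != bootstrap_ci(vals, seed=10)

    def test_less_than_two_subjects_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([0.5])

    def test_bernoulli_ci_approximates_exact_binomial_quantiles(self):
        from scipy.stats import binom

        values = np.array([0.0] * 50 + [1.0] * 50)
        lo, hi = bootstrap_ci(values, n_boot=10_000, seed=3)
        exact_lo = binom.ppf(0.025, 100, 0.5) / 100
        exact_hi = binom.ppf(0.975, 100, 0.5) / 100
        assert lo < 0.5 < hi
        assert lo == pytest.approx(exact_lo, abs=0.02)
        assert hi == pytest.approx(exact_hi, abs=0.02)


class TestEvaluateLMS:
    def test_identical_reports_give_perfect_metrics(self):
        rng = np.random.default_rng(4)
        refs = {
            f"case{i}": _report({r: int(rng.integers(0, 3)) for r in Region})
            for i in range(6)
        }
        confs, summary = evaluate_lms(refs, refs)
        vals = summary[["accuracy", "weighted_precision", "weighted_recall", "weighted_f1"]]
        assert np.allclose(vals, 1.0, atol=1e-12)
        assert set(summary["region"]) == {
            "frontal", "anterior_ethmoid", "posterior_ethmoid", "maxillary", "sphenoid", "omc"
        }
        assert all(c.total == 12 for c in confs.values())  # 6 cases x 2 sides

    def test_shifted_predictions_have_zero_accuracy(self):
        refs = {f"c{i}": _report({r: 0 for r in Region}) for i in range(3)}
        preds = {f"c{i}": _report({r: 1 for r in Region}) for i in range(3)}
        _, summary = evaluate_lms(refs, preds)
        assert (summary["accuracy"] == 0.0).all()

    def test_injected_error_rate_recovered_exactly(self):
        rng = np.random.default_rng(8)
        n_cases = 15
        refs, preds = {}, {}
        n_wrong = 0
        for i in range(n_cases):
            true = {r: int(rng.integers(0, 3)) for r in Region}
            pred = dict(true)
            for r in Region:  # 10% injected band errors
                if rng.random() < 0.1:
                    pred[r] = (true[r] + 1) % 3
                    n_wrong += 1
            refs[f"c{i}"] = _report(true)
            preds[f"c{i}"] = _report(pred)
        confs, _ = evaluate_lms(refs, preds)
        off_diag = sum(c.total - int(np.trace(c.counts)) for c in confs.values())
        assert off_diag == n_wrong

    def test_unpaired_cases_listed(self):
        refs = {"a": _report({}), "b": _report({})}
        preds = {"a": _report({})}
        with pytest.raises(ValueError, match="b"):
            evaluate_lms(refs, preds)

    def test_order_invariance(self):
        rng = np.random.default_rng(12)
        items = [
            (f"c{i}", _report({r: int(rng.integers(0, 3)) for r in Region}))
            for i in range(5)
        ]
        preds = {
            k: _report({r: max(0, v.sub_score - 1) for r, v in rep.scores.items()})
            for k, rep in items
        }
        refs_fwd = dict(items)
        refs_rev = dict(reversed(items))
        _, s1 = evaluate_lms(refs_fwd, preds)
        _, s2 = evaluate_lms(refs_rev, preds)
        assert s1.equals(s2)


def test_dice_table_schema_and_ci_ordering():
    import pandas as pd

    rng = np.random.default_rng(5)
    rows = []
    for subj in range(8):
        for sinus in ["frontal", "maxillary", "omc"]:
            rows.append({"subject": subj, "region": sinus, "dsc": rng.uniform(0.5, 1.0)})
    df = dice_table(pd.DataFrame(rows), n_boot=500, seed=0)
    assert list(df.columns) == ["region", "mean_dsc", "ci_low", "ci_high"]
    assert (df["ci_low"] <= df["mean_dsc"] + 1e-12).all()
    assert (df["mean_dsc"] <= df["ci_high"] + 1e-12).all()
    assert "mean_excluding_omc" in set(df["region"])
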