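"""Metrics, plaque attributes, agreement statistics, folds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octaline.data import ALineLabel
from octaline.evaluation import (
    arc_angle,
    bland_altman,
    circular_runs,
    confusion_metrics,
    make_folds,
    paired_wilcoxon,
    plaque_length,
    select_folds_for_relabeling,
)

GW = int(ALineLabel.GUIDEWIRE)


def brute_force_counts(pred, ref, code):
    """Literal one-vs-rest confusion counting, excluding guidewire cells."""
    tp = fp = fn = tn = 0
    for p, r in zip(pred.ravel(), ref.ravel()):
        if p == GW or r == GW:
            continue
        if p == code and r == code:
            tp += 1
        elif p == code:
            fp += 1
        elif r == code:
            fn += 1
        else:
            tn += 1
    return tp, tn, fp, fn


class TestConfusionMetrics:
    def test_formula_examples(self):
        pred = np.array([[0] * 9 + [2] + [0] * 0])  # TP=9, FN=1 for class 0
        ref = np.array([[0] * 10])
        rep = confusion_metrics(pred, ref)
        assert rep.per_class["FIBROLIPIDIC"]["sensitivity"] == pytest.approx(0.9)

    def test_f1_example(self):
        # TP=8, FP=2, FN=2 → F1 = 16/20
        pred = np.array([[0] * 8 + [0, 0] + [2, 2]])
        ref = np.array([[0] * 8 + [2, 2] + [0, 0]])
        rep = confusion_metrics(pred, ref)
        assert rep.per_class["FIBROLIPIDIC"]["f1"] == pytest.approx(0.8)

    def test_identity_prediction_perfect_scores(self, rng):
        labels = rng.integers(0, 3, size=(20, 10))
        rep = confusion_metrics(labels, labels)
        for cls in rep.per_class.values():
            assert cls["sensitivity"] == 1.0
            assert cls["specificity"] == 1.0
            assert cls["f1"] == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_random_grids_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.integers(0, 4, size=(20, 10))
        ref = rng.integers(0, 4, size=(20, 10))
        rep = confusion_metrics(pred, ref)
        for label in (ALineLabel.FIBROLIPIDIC, ALineLabel.FIBROCALCIFIC, ALineLabel.OTHER):
            tp, tn, fp, fn = brute_force_counts(pred, ref, int(label))
            got = rep.per_class[label.name]
            assert (got["tp"], got["tn"], got["fp"], got["fn"]) == (tp, tn, fp, fn)
            if tp + fn:
                assert got["sensitivity"] == pytest.approx(tp / (tp + fn))
                assert got["f1"] == pytest.approx(2 * tp / (2 * tp + fp + fn))
            assert got["specificity"] == pytest.approx(tn / (tn + fp))

    def test_counts_partition_evaluated_cells(self, rng):
        pred = rng.integers(0, 4, size=(16, 8))
        ref = rng.integers(0, 4, size=(16, 8))
        rep = confusion_metrics(pred, ref)
        for cls in rep.per_class.values():
            assert cls["tp"] + cls["tn"] + cls["fp"] + cls["fn"] == rep.n_evaluated

    def test_absent_class_sensitivity_missing_not_zero(self):
        pred = np.full((4, 4), 2)
        ref = np.full((4, 4), 2)
        rep = confusion_metrics(pred, ref)
        assert rep.per_class["FIBROLIPIDIC"]["sensitivity"] is None
        assert rep.per_class["FIBROLIPIDIC"]["f1"] is None

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(np.zeros((3, 3)), np.zeros((3, 4)))


def oracle_circular_runs(flags):
    """Doubling-trick oracle for circular run lengths."""
    n = len(flags)
    if all(flags):
        return [(0, n)]
    doubled = list(flags) + list(flags)
    runs = []
    i = 0
    while i < n:
        if doubled[i] and (i == 0 and not flags[-1] or i > 0 and not doubled[i - 1]):
            j = i
            while doubled[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return [(s, l) for s, l in runs if l <= n]


class TestArcAngle:
    def test_closed_form_quarter_arc(self):
        labels = np.full(496, 2)
        labels[100:224] = 1
        assert arc_angle(labels, ALineLabel.FIBROCALCIFIC) == [pytest.approx(90.0)]

    def test_wrap_around_is_single_run(self):
        labels = np.full(496, 2)
        labels[436:] = 0  # 60 A-lines at the end
        labels[:64] = 0  # 64 at the start
        arcs = arc_angle(labels, ALineLabel.FIBROLIPIDIC)
        assert arcs == [pytest.approx(90.0)]

    def test_all_classes_partition_circle(self, rng):
        labels = rng.integers(0, 4, size=96)
        total = sum(
            sum(arc_angle(labels, code)) for code in range(4)
        )
        assert total == pytest.approx(360.0)

    @given(st.lists(st.booleans(), min_size=4, max_size=24))
    @settings(deadline=None, max_examples=80)
    def test_circular_runs_match_doubling_oracle(self, flags):
        got = sorted(circular_runs(np.array(flags)))
        want = sorted(oracle_circular_runs(flags))
        assert sum(l for _, l in got) == sum(l for _, l in want)
        assert got == want


class TestPlaqueLength:
    def test_contiguous_run_times_interval(self):
        labels = np.full((4, 20), 2)
        labels[1, 5:15] = 0
        lengths = plaque_length(labels, ALineLabel.FIBROLIPIDIC, 0.2)
        assert lengths[1] == [pytest.approx(2.0)]
        assert lengths[0] == []

    def test_separated_runs(self):
        labels = np.full((1, 12), 2)
        labels[0, 1:4] = 1
        labels[0, 6:10] = 1
        lengths = plaque_length(labels, ALineLabel.FIBROCALCIFIC, 0.2)
        assert lengths[0] == [pytest.approx(0.6), pytest.approx(0.8)]

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            plaque_length(np.zeros((2, 2)), 0, 0.0)


class TestBlandAltman:
    def test_identical_pairs(self):
        out = bland_altman(np.arange(5.0), np.arange(5.0))
        assert out["bias"] == 0.0 and out["sd"] == 0.0

    def test_constant_offset(self):
        out = bland_altman(np.arange(5.0) + 5.0, np.arange(5.0))
        assert out["bias"] == pytest.approx(5.0)
        assert out["sd"] == 0.0

    def test_recovers_known_bias_within_sampling_error(self, rng):
        n, mu, sigma = 10_000, 2.5, 1.3
        ref = rng.normal(10, 3, n)
        pred = ref + rng.normal(mu, sigma, n)
        out = bland_altman(pred, ref)
        assert abs(out["bias"] - mu) <= 3 * sigma / np.sqrt(n)
        assert out["sd"] == pytest.approx(sigma, rel=0.05)
        assert out["upper_limit"] == pytest.approx(out["bias"] + 1.96 * out["sd"])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(np.array([1.0]), np.array([1.0]))


class TestPairedWilcoxon:
    def test_identical_vectors_degenerate_p_one(self):
        assert paired_wilcoxon(np.arange(6.0), np.arange(6.0)) == 1.0

    def test_exact_p_for_six_positive_differences(self):
        """All n = 6 differences positive: the two-sided exact p-value is
        2/2⁶ = 0.03125 (only the all-positive and all-negative sign
        assignments reach the extreme rank sum)."""
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        b = a - np.array([0.5, 0.6, 0.7, 0.8, 0.9, 1.0])
        assert paired_wilcoxon(a, b) == pytest.approx(2 / 64)

    def test_shift_invariance(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        assert paired_wilcoxon(a, b) == pytest.approx(paired_wilcoxon(a + 7.0, b + 7.0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_wilcoxon(np.zeros(3), np.zeros(4))


class TestMakeFolds:
    def test_five_folds_of_25_vois(self):
        ids = [f"v{i}" for i in range(25)]
        split = make_folds(ids, n_folds=5, seed=1)
        tested = [v for fold in split.folds for v in fold["test"]]
        assert sorted(tested) == sorted(ids)
        for fold in split.folds:
            assert len(fold["test"]) == 5
            assert len(fold["validation"]) == 5
            assert len(fold["train"]) == 15
            assert not (set(fold["train"]) & set(fold["test"]))
            assert not (set(fold["validation"]) & set(fold["test"]))

    def test_held_out_untouched(self):
        ids = [f"v{i}" for i in range(30)]
        split = make_folds(ids, n_folds=5, held_out_fraction=0.2, seed=2)
        assert len(split.held_out) == 6
        pooled = {v for fold in split.folds for k in fold for v in fold[k]}
        assert not (pooled & set(split.held_out))

    def test_deterministic_under_seed(self):
        ids = [f"v{i}" for i in range(20)]
        assert make_folds(ids, seed=7).folds == make_folds(ids, seed=7).folds

    def test_too_few_vois_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b", "c"], n_folds=5)


class TestFoldSelection:
    @pytest.mark.parametrize(
        "f1s, expected",
        [
            ([0.69, 0.80, 0.71], [0]),
            ([0.70, 0.80], []),  # strict inequality at the threshold
            ([0.9, 0.95, 0.99], []),
            ([0.5, 0.6, 0.9], [0, 1]),
        ],
    )
    def test_threshold_rule(self, f1s, expected):
        assert select_folds_for_relabeling(f1s) == expected
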