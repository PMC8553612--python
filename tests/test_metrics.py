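"""Confusion tallies, metric panel, AUC — with brute-force and sklearn oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from vepbench.constants import (
    DEL,
    TOL,
    CALL_DEL,
    CALL_TOL,
    CALL_INDETERMINATE,
    CALL_MISSING,
)
from vepbench.errors import DataError
from vepbench.metrics import (
    ConfusionCounts,
    auc,
    confusion_counts,
    mean_across_genes,
    median_score_by_class,
    metric_panel,
)

from conftest import make_calls, make_scores, make_truthset


def brute_confusion(calls, truth):
    """Naive loop oracle for the 2x2 tally."""
    tp = fp = tn = fn = 0
    for c, t in zip(calls, truth):
        if c == CALL_DEL and t == DEL:
            tp += 1
        elif c == CALL_DEL and t == TOL:
            fp += 1
        elif c == CALL_TOL and t == TOL:
            tn += 1
        elif c == CALL_TOL and t == DEL:
            fn += 1
    return (tp, fp, tn, fn)


def brute_auc(del_scores, tol_scores):
    """All-pairs concordance with ties counted one half."""
    wins = 0.0
    for d in del_scores:
        for t in tol_scores:
            wins += 1.0 if d > t else (0.5 if d == t else 0.0)
    return wins / (len(del_scores) * len(tol_scores))


class TestConfusionCounts:
    def test_mixed_example(self, small_truthset):
        c = confusion_counts(make_calls([CALL_DEL, CALL_DEL, CALL_TOL, CALL_TOL]),
                             small_truthset)
        assert c.as_tuple() == (1, 1, 1, 1)

    def test_all_correct(self):
        truth = make_truthset([DEL] * 10 + [TOL] * 90)
        calls = make_calls([CALL_DEL] * 10 + [CALL_TOL] * 90)
        c = confusion_counts(calls, truth)
        assert (c.tp, c.tn, c.fp, c.fn) == (10, 90, 0, 0)

    def test_exhaustive_call_vectors_match_naive_loop(self, small_truthset):
        """Every 4-variant call vector over {DEL,TOL,INDET} matches the oracle."""
        truth_labels = small_truthset.labels.tolist()
        for combo in itertools.product(
            [CALL_DEL, CALL_TOL, CALL_INDETERMINATE], repeat=4
        ):
            c = confusion_counts(make_calls(combo), small_truthset)
            assert c.as_tuple() == brute_confusion(combo, truth_labels)

    def test_indeterminate_and_missing_excluded(self, small_truthset):
        calls = make_calls([CALL_INDETERMINATE, CALL_MISSING,
                            CALL_INDETERMINATE, CALL_MISSING])
        assert confusion_counts(calls, small_truthset).empty

    def test_negative_cells_rejected(self):
        with pytest.raises(DataError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)


class TestMetricPanel:
    def test_published_sensitivity_specificity_ba(self):
        panel = metric_panel(ConfusionCounts(tp=92, fn=8, tn=66, fp=34))
        assert panel.sensitivity == pytest.approx(0.92)
        assert panel.specificity == pytest.approx(0.66)
        assert panel.balanced_accuracy == pytest.approx(0.79)

    def test_mcc_hand_computed(self):
        panel = metric_panel(ConfusionCounts(tp=92, fn=8, tn=66, fp=34))
        assert panel.mcc == pytest.approx(0.6007, abs=5e-5)

    def test_symmetric_counts(self):
        panel = metric_panel(ConfusionCounts(tp=25, fp=25, tn=25, fn=25))
        assert panel.sensitivity == panel.specificity == 0.5
        assert panel.balanced_accuracy == 0.5
        assert panel.mcc == pytest.approx(0.0)

    def test_zero_denominator_flagged_not_zero(self):
        # no called-DEL variants: PPV undefined, never silently zero
        panel = metric_panel(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert panel.ppv is None and not panel.defined("ppv")
        assert panel.specificity == 1.0

    def test_empty_counts_rejected(self):
        with pytest.raises(DataError):
            metric_panel(ConfusionCounts(0, 0, 0, 0))

    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50),
        tn=st.integers(0, 50), fn=st.integers(0, 50),
    )
    def test_ba_identity_and_prevalence_conservation(self, tp, fp, tn, fn):
        c = ConfusionCounts(tp, fp, tn, fn)
        if c.empty:
            return
        panel = metric_panel(c)
        if panel.sensitivity is not None and panel.specificity is not None:
            assert panel.balanced_accuracy == pytest.approx(
                (panel.sensitivity + panel.specificity) / 2
            )
        assert panel.prevalence * c.total == pytest.approx(tp + fn)

    @given(
        tp=st.integers(1, 50), fp=st.integers(1, 50),
        tn=st.integers(1, 50), fn=st.integers(1, 50),
    )
    def test_mcc_sign_flips_when_predictions_inverted(self, tp, fp, tn, fn):
        c = ConfusionCounts(tp, fp, tn, fn)
        mcc = metric_panel(c).mcc
        mcc_inv = metric_panel(c.calls_inverted()).mcc
        assert mcc_inv == pytest.approx(-mcc)


class TestAUC:
    def test_perfect_separation(self):
        ts = make_truthset([DEL, DEL, TOL, TOL])
        value, defined = auc(make_scores([0.9, 0.8, 0.1, 0.2]), ts)
        assert defined and value == 1.0

    def test_all_ties_half(self):
        ts = make_truthset([DEL, TOL, DEL, TOL])
        value, _ = auc(make_scores([0.5] * 4), ts)
        assert value == 0.5

    def test_three_of_four_pairs_concordant(self):
        ts = make_truthset([DEL, DEL, TOL, TOL])
        value, _ = auc(make_scores([0.8, 0.4, 0.6, 0.2]), ts)
        assert value == 0.75

    def test_direction_aware(self):
        ts = make_truthset([DEL, DEL, TOL, TOL])
        value, _ = auc(make_scores([0.1, 0.2, 0.8, 0.9]), ts,
                       direction="lower_is_deleterious")
        assert value == 1.0

    def test_single_class_undefined(self):
        ts = make_truthset([DEL, DEL])
        value, defined = auc(make_scores([0.1, 0.2]), ts)
        assert value is None and not defined

    def test_matches_brute_force_and_sklearn(self):
        """Rank AUC equals all-pairs concordance and sklearn on random inputs."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(4, 100))
            labels = rng.choice([DEL, TOL], size=n)
            if len(set(labels)) < 2:
                continue
            # ties made likely by rounding to one decimal
            values = np.round(rng.random(n), 1)
            ts = make_truthset(labels)
            ours, defined = auc(make_scores(values), ts)
            assert defined
            expected = brute_auc(values[labels == DEL], values[labels == TOL])
            assert ours == pytest.approx(expected)
            sk = roc_auc_score((labels == DEL).astype(int), values)
            assert ours == pytest.approx(sk)


class TestAggregation:
    def panels(self, *cells):
        return [metric_panel(ConfusionCounts(*c)) for c in cells]

    def test_mean_of_two(self):
        panels = self.panels((92, 34, 66, 8), (89, 32, 68, 11))
        mean = mean_across_genes(panels)
        expected = (panels[0].balanced_accuracy + panels[1].balanced_accuracy) / 2
        assert mean.balanced_accuracy == pytest.approx(expected)

    def test_undefined_metric_averaged_over_remaining(self):
        defined = self.panels((10, 5, 20, 3), (8, 4, 22, 5), (9, 6, 18, 2),
                              (7, 2, 25, 4))
        no_ppv = metric_panel(ConfusionCounts(tp=0, fp=0, tn=30, fn=5))
        mean = mean_across_genes(defined + [no_ppv])
        assert mean.n_contributing["ppv"] == 4
        assert mean.ppv == pytest.approx(np.mean([p.ppv for p in defined]))

    def test_five_equal_panels_identity(self):
        panels = self.panels(*[(10, 5, 20, 3)] * 5)
        mean = mean_across_genes(panels)
        assert mean.balanced_accuracy == pytest.approx(panels[0].balanced_accuracy)
        assert mean.mcc == pytest.approx(panels[0].mcc)

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            mean_across_genes([])


class TestMedianByClass:
    def test_del_tol_medians(self):
        scores = pd.Series([0.9, 0.8, 0.7, 0.1, 0.2, 0.3])
        classes = pd.Series([DEL] * 3 + [TOL] * 3)
        meds = median_score_by_class(scores, classes)
        assert meds[DEL] == pytest.approx(0.8)
        assert meds[TOL] == pytest.approx(0.2)

    def test_intermediate_between(self):
        scores = pd.Series([0.5, 0.6])
        classes = pd.Series(["INTERMEDIATE"] * 2)
        assert median_score_by_class(scores, classes)["INTERMEDIATE"] == pytest.approx(0.55)

    def test_single_score_and_empty_class_omitted(self):
        scores = pd.Series([0.4, np.nan])
        classes = pd.Series([DEL, TOL])
        meds = median_score_by_class(scores, classes)
        assert meds == {DEL: 0.4}
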