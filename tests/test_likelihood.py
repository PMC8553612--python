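"""Likelihood ratios: Haldane correction, CIs, reciprocity, banded analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from vepbench.constants import DEL, TOL
from vepbench.errors import DataError
from vepbench.likelihood import (
    BandDefinition,
    banded_lr,
    conventional_nlr,
    default_bands,
    haldane_correct,
    likelihood_ratios,
    mean_lr_across_genes,
)
from vepbench.metrics import ConfusionCounts

from conftest import make_scores, make_truthset


class TestHaldane:
    def test_zero_cell_adds_half_everywhere(self):
        corrected, applied = haldane_correct(ConfusionCounts(10, 0, 5, 20))
        assert applied
        assert corrected.as_tuple() == (10.5, 0.5, 5.5, 20.5)

    def test_no_zero_identity(self):
        c = ConfusionCounts(10, 1, 5, 20)
        corrected, applied = haldane_correct(c)
        assert not applied and corrected == c

    def test_all_zero(self):
        corrected, applied = haldane_correct(ConfusionCounts(0, 0, 0, 0))
        assert applied and corrected.as_tuple() == (0.5, 0.5, 0.5, 0.5)

    @given(
        tp=st.integers(0, 20), fp=st.integers(0, 20),
        tn=st.integers(0, 20), fn=st.integers(0, 20),
    )
    def test_idempotence(self, tp, fp, tn, fn):
        once, _ = haldane_correct(ConfusionCounts(tp, fp, tn, fn))
        twice, applied_again = haldane_correct(once)
        assert not applied_again and twice == once


class TestLikelihoodRatios:
    def test_plr_hand_computed(self):
        plr, _ = likelihood_ratios(ConfusionCounts(tp=92, fn=8, tn=66, fp=34))
        assert plr.estimate == pytest.approx(0.92 / 0.34, rel=1e-9)

    def test_nlr_hand_computed_benignity_scale(self):
        _, nlr = likelihood_ratios(ConfusionCounts(tp=92, fn=8, tn=66, fp=34))
        assert nlr.estimate == pytest.approx(0.66 / 0.08, rel=1e-9)
        assert conventional_nlr(nlr) == pytest.approx(0.08 / 0.66, rel=1e-9)

    def test_no_discrimination_gives_unity(self):
        plr, nlr = likelihood_ratios(ConfusionCounts(25, 25, 25, 25))
        assert plr.estimate == pytest.approx(1.0)
        assert nlr.estimate == pytest.approx(1.0)

    def test_ci_brackets_estimate_and_log_se_formula(self):
        c = ConfusionCounts(tp=92, fn=8, tn=66, fp=34)
        plr, _ = likelihood_ratios(c)
        se = np.sqrt(1 / 92 - 1 / 100 + 1 / 34 - 1 / 100)
        assert plr.ci_low == pytest.approx(plr.estimate * np.exp(-1.959963984540054 * se))
        assert plr.ci_high == pytest.approx(plr.estimate * np.exp(1.959963984540054 * se))

    def test_zero_cell_takes_haldane_path(self):
        plr, nlr = likelihood_ratios(ConfusionCounts(tp=10, fp=0, tn=20, fn=5))
        assert plr.haldane_applied and np.isfinite(plr.estimate)
        assert plr.estimate > 1

    @given(
        tp=st.integers(0, 30), fp=st.integers(0, 30),
        tn=st.integers(0, 30), fn=st.integers(0, 30),
    )
    def test_reciprocity_under_call_inversion(self, tp, fp, tn, fn):
        c = ConfusionCounts(tp, fp, tn, fn)
        if c.empty:
            return
        plr, nlr = likelihood_ratios(c)
        plr_inv, nlr_inv = likelihood_ratios(c.inverted())
        assert plr_inv.estimate == pytest.approx(nlr.estimate)
        assert nlr_inv.estimate == pytest.approx(plr.estimate)
        assert plr_inv.ci_low == pytest.approx(nlr.ci_low)
        assert plr_inv.ci_high == pytest.approx(nlr.ci_high)


class TestBandedLR:
    def test_direct_two_by_two(self):
        # DEL: 8 in band, 2 in reference; TOL: 1 in band, 9 in reference
        scores = make_scores([0.9] * 8 + [0.1] * 2 + [0.9] * 1 + [0.1] * 9)
        ts = make_truthset([DEL] * 10 + [TOL] * 10)
        band = BandDefinition(0.8, 1.0, "<", 0.7, kind="PLR")
        res, defined = banded_lr(scores, ts, band)
        assert defined
        assert res.estimate == pytest.approx((8 / 10) / (1 / 10))

    def test_between_band_and_reference_excluded(self):
        # variants at 0.75 fall in neither region and must not contribute
        scores = make_scores([0.9, 0.75, 0.1, 0.75, 0.9, 0.1])
        ts = make_truthset([DEL, DEL, DEL, TOL, TOL, TOL])
        band = BandDefinition(0.8, 1.0, "<", 0.7, kind="PLR")
        res, _ = banded_lr(scores, ts, band)
        assert res.counts_used.total == 4

    def test_haldane_path_when_band_pure(self):
        scores = make_scores([0.9] * 5 + [0.1] * 5)
        ts = make_truthset([DEL] * 5 + [TOL] * 5)
        band = BandDefinition(0.8, 1.0, "<", 0.7, kind="PLR")
        res, _ = banded_lr(scores, ts, band)
        assert res.haldane_applied and np.isfinite(res.estimate)
        assert res.estimate > 1

    def test_degenerate_band_equals_binary_plr(self):
        rng = np.random.default_rng(3)
        labels = [DEL] * 40 + [TOL] * 60
        vals = np.concatenate([rng.beta(6, 2, 40), rng.beta(2, 6, 60)])
        scores = make_scores(vals)
        ts = make_truthset(labels)
        # band = entire region above 0.7, reference = everything at/below
        band = BandDefinition(np.nextafter(0.7, 1), 1.0, "<=", 0.7, kind="PLR")
        res, _ = banded_lr(scores, ts, band)
        calls_del = vals > 0.7
        c = ConfusionCounts(
            tp=int((calls_del & (np.array(labels) == DEL)).sum()),
            fp=int((calls_del & (np.array(labels) == TOL)).sum()),
            fn=int((~calls_del & (np.array(labels) == DEL)).sum()),
            tn=int((~calls_del & (np.array(labels) == TOL)).sum()),
        )
        plr, _ = likelihood_ratios(c)
        assert res.estimate == pytest.approx(plr.estimate)

    def test_benignity_band_is_tol_over_del(self):
        # low band vs reference >0.7: ratio of TOL in band over DEL in band
        scores = make_scores([0.2] * 9 + [0.9] * 1 + [0.2] * 2 + [0.9] * 8)
        ts = make_truthset([TOL] * 10 + [DEL] * 10)
        band = BandDefinition(0.0, 0.4, ">", 0.7, kind="NLR")
        res, _ = banded_lr(scores, ts, band)
        assert res.estimate == pytest.approx((9 / 10) / (2 / 10))

    def test_empty_regions_undefined(self):
        scores = make_scores([0.5, 0.6])
        ts = make_truthset([DEL, TOL])
        band = BandDefinition(0.9, 1.0, "<", 0.2, kind="PLR")
        res, defined = banded_lr(scores, ts, band)
        assert res is None and not defined

    def test_band_reference_overlap_rejected(self):
        with pytest.raises(DataError):
            BandDefinition(0.5, 1.0, "<", 0.7, kind="PLR")

    def test_default_band_layout(self):
        bands = default_bands(0.7)
        assert len(bands) == 8
        assert {b.kind for b in bands} == {"PLR", "NLR"}

    def test_widening_band_approaches_binary_plr(self):
        """Widening toward the full positive region moves the LR toward binary."""
        rng = np.random.default_rng(9)
        labels = [DEL] * 300 + [TOL] * 700
        vals = np.concatenate([rng.beta(8, 2, 300), rng.beta(2, 8, 700)])
        scores = make_scores(vals)
        ts = make_truthset(labels)
        widths = [(0.95, 1.0), (0.85, 1.0), (0.75, 1.0), (np.nextafter(0.7, 1), 1.0)]
        estimates = []
        for lo, hi in widths:
            res, defined = banded_lr(scores, ts, BandDefinition(lo, hi, "<=", 0.7))
            assert defined
            estimates.append(res.estimate)
        binary = estimates[-1]
        gaps = [abs(e - binary) for e in estimates]
        assert gaps[-1] == 0
        assert gaps[0] >= gaps[-2] >= gaps[-1]


class TestMeanAcrossGenes:
    def make_lr(self, est, lo=None, hi=None):
        from vepbench.likelihood import LRResult

        return LRResult("PLR", est, lo if lo is not None else est / 2,
                        hi if hi is not None else est * 2, False,
                        ConfusionCounts(1, 1, 1, 1))

    def test_arithmetic_mean(self):
        mean = mean_lr_across_genes([self.make_lr(2.0), self.make_lr(4.0)])
        assert mean.estimate == pytest.approx(3.0)
        assert mean.ci_low == pytest.approx(1.5)
        assert mean.ci_high == pytest.approx(6.0)

    def test_single_gene_identity(self):
        lr = self.make_lr(5.0)
        mean = mean_lr_across_genes([lr])
        assert (mean.estimate, mean.ci_low, mean.ci_high) == (
            lr.estimate, lr.ci_low, lr.ci_high
        )

    def test_five_equal(self):
        mean = mean_lr_across_genes([self.make_lr(3.0)] * 5)
        assert mean.estimate == pytest.approx(3.0)

    def test_log_pooling_is_geometric_mean(self):
        mean = mean_lr_across_genes(
            [self.make_lr(2.0), self.make_lr(8.0)], pooling="log"
        )
        assert mean.estimate == pytest.approx(4.0)

    def test_mixed_kinds_rejected(self):
        from vepbench.likelihood import LRResult

        plr = self.make_lr(2.0)
        nlr = LRResult("NLR", 2.0, 1.0, 4.0, False, ConfusionCounts(1, 1, 1, 1))
        with pytest.raises(DataError):
            mean_lr_across_genes([plr, nlr])


def test_ci_coverage_on_simulated_tables():
    """95% log-SE interval covers the true PLR in 93–97% of 2,000 tables."""
    rng = np.random.default_rng(2024)
    sens0, spec0 = 0.85, 0.75
    true_plr = sens0 / (1 - spec0)
    n_del, n_tol = 120, 200
    covered = 0
    n_rep = 2000
    for _ in range(n_rep):
        tp = rng.binomial(n_del, sens0)
        tn = rng.binomial(n_tol, spec0)
        c = ConfusionCounts(tp=tp, fn=n_del - tp, tn=tn, fp=n_tol - tn)
        plr, _ = likelihood_ratios(c)
        if plr.ci_low <= true_plr <= plr.ci_high:
            covered += 1
    assert 0.93 <= covered / n_rep <= 0.97
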