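import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epnmethyl.classifier import (
    GENES,
    BetaFit,
    ConfusionMatrix,
    ThresholdRule,
    evaluate,
    fit_beta,
    lr_threshold,
    predict,
    predict_all,
    select_rule,
    stratified_split,
)
from epnmethyl.errors import DegenerateFitError, NoCrossoverError, ValidationError
from conftest import gene_panel_cohort


def panel_frame(rows):
    """rows: (sample_id, crip1, drd4, lbx2, subgroup)."""
    return pd.DataFrame(rows, columns=["sample_id", *GENES, "subgroup"])


class TestStratifiedSplit:
    def test_published_cohort_arithmetic(self):
        panel = gene_panel_cohort(n_pfa=90, n_pfb=33, seed=0)
        train, validation = stratified_split(panel, train_fraction=1 / 3, seed=0)
        assert len(train) == 41 and len(validation) == 82
        assert train["subgroup"].value_counts().to_dict() == {"PFA": 30, "PFB": 11}
        assert validation["subgroup"].value_counts().to_dict() == {"PFA": 60, "PFB": 22}
        assert set(train.sample_id).isdisjoint(validation.sample_id)
        assert len(train) + len(validation) == len(panel)

    def test_degenerate_stratum_rejected_unless_allowed(self):
        panel = panel_frame([("a", 50, 50, 50, "PFA"), ("b", 55, 55, 55, "PFA"),
                             ("c", 5, 5, 5, "PFB")])
        with pytest.raises(ValidationError, match="absent from a partition"):
            stratified_split(panel, train_fraction=1 / 3, seed=0)
        train, validation = stratified_split(panel, train_fraction=1 / 3, seed=0,
                                             allow_empty_class=True)
        assert len(train) == 1 and len(validation) == 2

    def test_membership_depends_only_on_seed(self):
        panel = gene_panel_cohort(n_pfa=20, n_pfb=10, seed=4)
        t1, _ = stratified_split(panel, seed=7)
        shuffled = panel.sample(frac=1.0, random_state=99).reset_index(drop=True)
        t2, _ = stratified_split(shuffled, seed=7)
        assert set(t1.sample_id) == set(t2.sample_id)
        t3, _ = stratified_split(panel, seed=8)
        assert set(t1.sample_id) != set(t3.sample_id)

    def test_unlabeled_record_rejected(self):
        panel = panel_frame([("a", 50, 50, 50, "PFA"), ("b", 5, 5, 5, None)])
        with pytest.raises(ValidationError):
            stratified_split(panel)


class TestFitBeta:
    def test_parameter_recovery_at_n_1000(self, rng):
        values = 100 * rng.beta(8, 6, 1000)
        fit = fit_beta(values, "CRIP1", "PFA")
        assert abs(fit.alpha - 8) / 8 < 0.15
        assert abs(fit.beta - 6) / 6 < 0.15

    def test_identical_values_are_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_beta([50.0] * 10, "DRD4", "PFA")

    def test_fitted_mean_tracks_sample_mean(self, rng):
        for a, b in [(8, 6), (1, 15), (2, 2)]:
            values = 100 * rng.beta(a, b, 200)
            fit = fit_beta(values, "LBX2", "PFB" if a < b else "PFA")
            clipped = np.clip(values / 100, 1e-3, 1 - 1e-3)
            assert abs(fit.mean - clipped.mean()) < 0.02

    def test_boundary_values_survive_clipping(self):
        fit = fit_beta([0.0, 0.0, 1.0, 2.0, 5.0, 100.0], "CRIP1", "PFB")
        assert fit.alpha > 0 and fit.beta > 0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValidationError):
            fit_beta([50.0], "CRIP1", "PFA")


class TestLrThreshold:
    def test_mirror_symmetric_fits_cross_at_midpoint(self):
        pfa = BetaFit("g", "PFA", 6, 2, 10)
        pfb = BetaFit("g", "PFB", 2, 6, 10)
        assert lr_threshold(pfa, pfb) == pytest.approx(50.0, abs=1e-6)

    def test_matches_fine_grid_brute_force(self):
        pfa = BetaFit("g", "PFA", 8, 6, 10)
        pfb = BetaFit("g", "PFB", 1, 15, 10)
        found = lr_threshold(pfa, pfb)
        # exhaustive scan at 1e-4 resolution on (0, 1)
        x = np.arange(1e-4, 1.0, 1e-4)
        d = stats.beta.logpdf(x, 8, 6) - stats.beta.logpdf(x, 1, 15)
        i = int(np.flatnonzero(np.sign(d[:-1]) * np.sign(d[1:]) < 0)[0])
        assert abs(found / 100 - x[i]) <= 1e-4

    def test_identical_fits_never_cross(self):
        pfa = BetaFit("g", "PFA", 5, 3, 10)
        with pytest.raises((NoCrossoverError, ValidationError)):
            lr_threshold(pfa, BetaFit("g", "PFB", 5, 3, 10))

    def test_wrong_mean_order_rejected(self):
        with pytest.raises(ValidationError):
            lr_threshold(BetaFit("g", "PFA", 2, 6, 10), BetaFit("g", "PFB", 6, 2, 10))

    @pytest.mark.parametrize("shapes", [((8, 6), (1, 15)), ((6, 2), (2, 6)),
                                        ((10, 10), (2, 18)), ((5, 4), (1, 9))])
    def test_threshold_lies_between_the_means(self, shapes):
        (a1, b1), (a2, b2) = shapes
        pfa, pfb = BetaFit("g", "PFA", a1, b1, 10), BetaFit("g", "PFB", a2, b2, 10)
        t = lr_threshold(pfa, pfb) / 100
        assert pfb.mean < t < pfa.mean


class TestPredict:
    RULE = {"CRIP1": 25.0, "DRD4": 11.0, "LBX2": 23.0}

    def make(self, mode):
        return ThresholdRule(thresholds=self.RULE, mode=mode)

    def test_all_genes_below_thresholds_is_pfb_under_every_mode(self):
        record = {"CRIP1": 10, "DRD4": 5, "LBX2": 15}
        for mode in ("all", "majority", "any"):
            assert predict(self.make(mode), record) == "PFB"

    def test_one_gene_above_threshold_splits_the_modes(self):
        record = {"CRIP1": 10, "DRD4": 50, "LBX2": 15}
        assert predict(self.make("all"), record) == "PFA"
        assert predict(self.make("majority"), record) == "PFB"
        assert predict(self.make("any"), record) == "PFB"

    def test_boundary_values_are_not_below(self):
        record = {"CRIP1": 25.0, "DRD4": 11.0, "LBX2": 23.0}
        for mode in ("all", "majority", "any"):
            assert predict(self.make(mode), record) == "PFA"

    def test_missing_gene_rejected(self):
        with pytest.raises(ValidationError):
            predict(self.make("all"), {"CRIP1": 10, "DRD4": 5})

    def test_pfb_call_sets_nest_across_modes(self):
        panel = gene_panel_cohort(n_pfa=60, n_pfb=30, seed=13)
        calls = {mode: set(panel.loc[
            predict_all(self.make(mode), panel) == "PFB", "sample_id"])
            for mode in ("all", "majority", "any")}
        assert calls["all"] <= calls["majority"] <= calls["any"]


class TestEvaluate:
    def test_printed_cohort_counts(self):
        truths = ["PFA"] * 29 + ["PFB"] * 15
        preds = ["PFA"] * 29 + ["PFB"] * 13 + ["PFA"] * 2
        cm = evaluate(preds, truths)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (13, 0, 29, 2)
        assert cm.specificity == 1.0
        assert cm.sensitivity == pytest.approx(13 / 15)

    def test_perfect_predictions(self):
        cm = evaluate(["PFA", "PFB"], ["PFA", "PFB"])
        assert cm.fp == cm.fn == 0 and cm.sensitivity == cm.specificity == 1.0

    def test_all_pfa_predictions_are_vacuously_specific(self):
        cm = evaluate(["PFA"] * 5, ["PFA", "PFA", "PFB", "PFB", "PFB"])
        assert cm.specificity == 1.0 and cm.sensitivity == 0.0

    def test_counts_sum_and_convention_swap_transposes(self):
        rng = np.random.default_rng(3)
        truths = list(rng.choice(["PFA", "PFB"], 40))
        preds = list(rng.choice(["PFA", "PFB"], 40))
        cm = evaluate(preds, truths)
        assert cm.total == 40
        swap = {"PFA": "PFB", "PFB": "PFA"}
        cm2 = evaluate([swap[p] for p in preds], [swap[t] for t in truths])
        assert (cm2.tp, cm2.fp, cm2.tn, cm2.fn) == (cm.tn, cm.fn, cm.tp, cm.fp)

    def test_undefined_rate_is_absent_not_zero(self):
        cm = evaluate(["PFA"], ["PFA"])
        assert cm.sensitivity is None and cm.specificity == 1.0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            evaluate(["PFC"], ["PFA"])


class TestSelectRule:
    THRESHOLDS = {"CRIP1": 25.0, "DRD4": 11.0, "LBX2": 23.0}

    def candidates(self):
        return [ThresholdRule(thresholds=self.THRESHOLDS, mode=m)
                for m in ("all", "majority", "any")]

    def test_well_separated_cohort_selects_all_mode(self):
        train = gene_panel_cohort(n_pfa=30, n_pfb=11, seed=1)
        validation = gene_panel_cohort(n_pfa=60, n_pfb=22, seed=2)
        rule = select_rule(self.candidates(), train, validation)
        assert rule.mode == "all"

    def test_single_candidate_returned_unchanged(self):
        train = gene_panel_cohort(n_pfa=10, n_pfb=5, seed=1)
        only = ThresholdRule(thresholds=self.THRESHOLDS, mode="any")
        assert select_rule([only], train, train) is only

    def test_tie_broken_toward_all(self):
        # every record far from all thresholds: the three modes agree exactly
        train = panel_frame([("a", 90, 90, 90, "PFA"), ("b", 1, 1, 1, "PFB"),
                             ("c", 85, 85, 85, "PFA"), ("d", 2, 2, 2, "PFB")])
        rule = select_rule(self.candidates(), train, train)
        assert rule.mode == "all"

    def test_empty_candidate_list_rejected(self):
        train = gene_panel_cohort(n_pfa=5, n_pfb=5, seed=1)
        with pytest.raises(ValidationError):
            select_rule([], train, train)

    def test_specificity_ordering_across_modes(self):
        panel = gene_panel_cohort(n_pfa=60, n_pfb=30, seed=17)
        specs, senss = [], []
        for mode in ("all", "majority", "any"):
            rule = ThresholdRule(thresholds=self.THRESHOLDS, mode=mode)
            cm = evaluate(predict_all(rule, panel), panel["subgroup"])
            specs.append(cm.specificity)
            senss.append(cm.sensitivity)
        assert specs[0] >= specs[1] >= specs[2]
        assert senss[0] <= senss[1] <= senss[2]


def test_rule_rejects_out_of_range_thresholds():
    with pytest.raises(ValidationError):
        ThresholdRule(thresholds={"CRIP1": 0.0, "DRD4": 11, "LBX2": 23}, mode="all")
    with pytest.raises(ValidationError):
        ThresholdRule(thresholds={"CRIP1": 25, "DRD4": 11, "LBX2": 23}, mode="most")


def test_confusion_matrix_rates_in_unit_interval():
    cm = ConfusionMatrix(tp=3, fp=1, tn=5, fn=2)
    assert 0 <= cm.sensitivity <= 1 and 0 <= cm.specificity <= 1
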