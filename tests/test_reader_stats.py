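"""Observer-study statistics: confusion, rates, bootstrap, kappa, chi2, Likert."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nodulefab import (
    ConfusionMatrix,
    ResponseRecipe,
    bootstrap_ci,
    chi2_goodness_of_fit,
    classification_rates,
    confidence_summary,
    conger_kappa,
    printed_count_fixtures,
    ratings_table,
    tabulate_confusion,
)
from nodulefab.errors import DomainError, EmptySelectionError
from nodulefab.reader_stats import RESPONSE_COLUMNS
from nodulefab.synthetic import make_synthetic_responses


def responses_from_counts(tp, fp, fn, tn):
    rows = []
    for truth, call, n in (
        ("printed", "printed", tp),
        ("patient", "printed", fp),
        ("printed", "patient", fn),
        ("patient", "patient", tn),
    ):
        for i in range(n):
            rows.append(("R01", "senior", f"C{len(rows)}", 1, truth, call, 3))
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)


class TestConfusion:
    def test_published_overall_counts(self, guessing_responses):
        fx = printed_count_fixtures()
        assert (fx["overall"].tp, fx["overall"].fp, fx["overall"].fn, fx["overall"].tn) == (
            375, 159, 339, 198
        )

    def test_tabulation_from_responses(self):
        df = responses_from_counts(3, 2, 1, 4)
        cm = tabulate_confusion(df)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (3, 2, 1, 4)

    def test_perfect_reader_has_no_errors(self):
        df = responses_from_counts(5, 0, 0, 5)
        cm = tabulate_confusion(df)
        assert cm.fp == cm.fn == 0

    def test_empty_experience_subset_raises(self):
        df = responses_from_counts(1, 1, 1, 1)
        with pytest.raises(EmptySelectionError):
            tabulate_confusion(df, experience="resident")


class TestRates:
    def test_published_overall_rates(self):
        r = classification_rates(printed_count_fixtures()["overall"])
        assert (r.accuracy, r.tpr, r.tnr, r.fnr, r.fpr) == (53.5, 52.5, 55.5, 47.5, 44.5)

    def test_published_subgroup_rates(self):
        fx = printed_count_fixtures()
        senior = classification_rates(fx["senior"])
        resident = classification_rates(fx["resident"])
        assert (senior.accuracy, senior.fnr) == (45.4, 57.6)
        assert (resident.tnr, resident.fnr) == (57.1, 43.3)

    def test_two_sample_perfect_case(self):
        r = classification_rates(ConfusionMatrix(1, 0, 0, 1))
        assert r.accuracy == 100.0
        assert (r.tpr, r.tnr, r.fpr, r.fnr) == (100.0, 100.0, 0.0, 0.0)

    def test_absent_class_rates_undefined_not_zero(self):
        r = classification_rates(ConfusionMatrix(tp=5, fp=0, fn=2, tn=0))
        assert r.tnr is None and r.fpr is None
        assert r.tpr is not None

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 500)] * 4))
    def test_rate_complementarity(self, counts):
        tp, fp, fn, tn = counts
        if tp + fp + fn + tn == 0:
            return
        r = classification_rates(ConfusionMatrix(tp, fp, fn, tn))
        if r.tpr is not None:
            assert r.tpr + r.fnr == pytest.approx(100.0, abs=0.1)
        if r.tnr is not None:
            assert r.tnr + r.fpr == pytest.approx(100.0, abs=0.1)


class TestBootstrap:
    def test_degenerate_all_correct(self):
        df = responses_from_counts(60, 0, 0, 60)
        assert bootstrap_ci(df, "accuracy", B=200, seed=0) == (100.0, 100.0)

    def test_interval_width_near_normal_approximation(self):
        rng = np.random.default_rng(5)
        n = 1000
        truth = np.where(rng.random(n) < 0.5, "printed", "patient")
        correct = rng.random(n) < 0.5
        call = np.where(
            correct, truth, np.where(truth == "printed", "patient", "printed")
        )
        df = pd.DataFrame(
            {
                "reader_id": "R01",
                "experience": "senior",
                "case_id": [f"C{i}" for i in range(n)],
                "presentation": 1,
                "truth": truth,
                "call": call,
                "confidence": 3,
            }
        )
        lo, hi = bootstrap_ci(df, "accuracy", B=2000, seed=11)
        # 2 * 1.96 * sqrt(0.25/1000) ~ 0.062 on the proportion scale
        assert 4.0 <= hi - lo <= 9.0

    def test_same_seed_reproduces_interval(self, guessing_responses):
        a = bootstrap_ci(guessing_responses, "tpr", B=300, seed=21)
        b = bootstrap_ci(guessing_responses, "tpr", B=300, seed=21)
        assert a == b

    def test_reader_and_case_units_run(self, guessing_responses):
        for unit in ("reader", "case"):
            lo, hi = bootstrap_ci(guessing_responses, "accuracy", unit=unit, B=150, seed=2)
            assert 0.0 <= lo <= hi <= 100.0

    def test_too_few_replicates_rejected(self, guessing_responses):
        with pytest.raises(DomainError):
            bootstrap_ci(guessing_responses, "accuracy", B=50)


class TestKappa:
    def test_perfect_agreement(self):
        table = np.array([[1, 1, 1], [2, 2, 2], [1, 1, 1], [2, 2, 2]])
        assert conger_kappa(table).kappa == pytest.approx(1.0)

    def test_two_rater_hand_example(self):
        # Po = 3/4, Pe = 0.5 -> kappa = 0.5 (equals Cohen's kappa)
        table = np.array([[1, 1], [1, 2], [2, 2], [2, 2]])
        assert conger_kappa(table).kappa == pytest.approx(0.5)

    def test_constant_table_undefined(self):
        table = np.full((4, 3), "printed")
        assert np.isnan(conger_kappa(table).kappa)

    def test_reduces_to_cohen_on_random_tables(self, rng):
        def cohen(a, b):
            cats = np.unique(np.concatenate([a, b]))
            po = np.mean(a == b)
            pe = sum(np.mean(a == c) * np.mean(b == c) for c in cats)
            return (po - pe) / (1 - pe)

        for _ in range(100):
            n = rng.integers(4, 12)
            k = rng.integers(2, 4)
            a = rng.integers(0, k, n)
            b = rng.integers(0, k, n)
            if np.all(a == a[0]) and np.all(b == a[0]):
                continue
            pe_check = conger_kappa(np.stack([a, b], axis=1))
            if np.isnan(pe_check.kappa):
                continue
            assert pe_check.kappa == pytest.approx(cohen(a, b), abs=1e-12)

    def test_guessing_readers_near_zero(self):
        recipe = ResponseRecipe(
            sensitivity={"senior": 0.5, "resident": 0.5},
            specificity={"senior": 0.5, "resident": 0.5},
            seed=7,
        )
        df = make_synthetic_responses(recipe)
        table = ratings_table(df)
        res = conger_kappa(table)
        assert res.n_raters == 17 and res.n_items == 63
        assert abs(res.kappa) < 0.05


class TestChi2:
    def test_exact_fit_gives_zero(self):
        g = chi2_goodness_of_fit(50, 50, 0.5)
        assert g.statistic == 0.0 and g.p_value == pytest.approx(1.0)

    def test_overall_correct_incorrect_split(self):
        g = chi2_goodness_of_fit(573, 498, 0.5)
        assert g.statistic == pytest.approx(5.2521008, abs=1e-6)
        assert g.df == 1

    def test_senior_split(self):
        g = chi2_goodness_of_fit(143, 172, 0.5)
        assert g.statistic == pytest.approx(2.6698413, abs=1e-6)

    def test_invalid_null_rejected(self):
        with pytest.raises(DomainError):
            chi2_goodness_of_fit(10, 10, 1.0)


class TestConfidence:
    def test_identical_distributions_give_unit_ratios(self):
        rows = []
        for conf in (2, 2, 3, 4):
            rows.append(("R1", "senior", f"A{conf}{len(rows)}", 1, "printed", "printed", conf))
            rows.append(("R1", "senior", f"B{conf}{len(rows)}", 1, "printed", "patient", conf))
        df = pd.DataFrame(rows, columns=RESPONSE_COLUMNS)
        out = confidence_summary(df)
        present = out["count"] > 0
        assert np.allclose(out.loc[present, "likelihood_ratio"], 1.0)

    def test_point_mass_at_level_five(self):
        df = responses_from_counts(4, 0, 0, 4).assign(confidence=5)
        out = confidence_summary(df)
        assert out.loc[5, "count"] == 8
        assert out.loc[5, "prop_correct"] == 1.0

    def test_hand_computed_likelihood_ratio(self):
        rows = []
        for conf, n_corr, n_inc in ((4, 10, 5), (2, 10, 15)):
            for i in range(n_corr):
                rows.append(("R1", "senior", f"c{conf}{i}", 1, "printed", "printed", conf))
            for i in range(n_inc):
                rows.append(("R1", "senior", f"i{conf}{i}", 1, "printed", "patient", conf))
        df = pd.DataFrame(rows, columns=RESPONSE_COLUMNS)
        out = confidence_summary(df)
        assert out.loc[4, "likelihood_ratio"] == pytest.approx(2.0)

    def test_absent_level_in_one_group_is_nan_not_inf(self):
        rows = [
            ("R1", "senior", "a", 1, "printed", "printed", 5),
            ("R1", "senior", "b", 1, "printed", "patient", 2),
        ]
        df = pd.DataFrame(rows, columns=RESPONSE_COLUMNS)
        out = confidence_summary(df)
        assert np.isnan(out.loc[5, "likelihood_ratio"])
        assert out.loc[5, "count"] == 1
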