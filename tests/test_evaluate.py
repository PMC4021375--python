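import math
import random

import numpy as np
import pytest

from indelrules.datamodel import (
    FeatureSchema,
    LabeledDataset,
    Record,
    RunConfig,
    ValidationError,
)
from indelrules.evaluate import (
    ConfusionCounts,
    af_reliability,
    assess_rules,
    chi_square_compare,
    confusion,
    cross_validate,
    format_percent,
    metrics,
    predict,
    rule_confusion,
    total_precision,
)
from indelrules.learner import Rule, RuleSet
from indelrules.simulate import default_planted_spec, generate_dataset

from conftest import make_dataset


def brute_force_metrics(pairs):
    """Independent recount of the confusion statistics from raw
    (label, prediction) pairs."""
    tp = sum(1 for l, p in pairs if l == "deleterious" and p == "deleterious")
    fp = sum(1 for l, p in pairs if l == "neutral" and p == "deleterious")
    tn = sum(1 for l, p in pairs if l == "neutral" and p == "neutral")
    fn = sum(1 for l, p in pairs if l == "deleterious" and p == "neutral")
    out = {}
    out["accuracy"] = (tp + tn) / len(pairs)
    out["sensitivity"] = tp / (tp + fn) if tp + fn else math.nan
    out["specificity"] = tn / (tn + fp) if tn + fp else math.nan
    out["precision"] = tp / (tp + fp) if tp + fp else math.nan
    out["npv"] = tn / (tn + fn) if tn + fn else math.nan
    d = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    out["mcc"] = (tp * tn - fp * fn) / math.sqrt(d) if d else math.nan
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn), out


class TestMetrics:
    def test_spot_check_precision_rendering(self):
        report = metrics(ConfusionCounts(tp=27, fp=5, tn=0, fn=0))
        assert report.precision == pytest.approx(0.84375)
        assert format_percent(report.precision) == "84.38"

    def test_perfect_classifier(self):
        report = metrics(ConfusionCounts(tp=10, fp=0, tn=10, fn=0))
        assert report.accuracy == report.sensitivity == report.mcc == 1.0

    def test_all_ones_confusion(self):
        report = metrics(ConfusionCounts(tp=1, fp=1, tn=1, fn=1))
        assert report.accuracy == pytest.approx(0.5)
        assert report.mcc == pytest.approx(0.0)

    def test_undefined_denominator_reported_as_nan(self):
        report = metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert math.isnan(report.precision)
        assert math.isnan(report.sensitivity)
        assert format_percent(report.precision) == "NA"

    @pytest.mark.parametrize("trial", range(20))
    def test_agrees_with_brute_force_recount(self, trial):
        rnd = random.Random(trial)
        pairs = [
            (rnd.choice(["deleterious", "neutral"]),
             rnd.choice(["deleterious", "neutral"]))
            for _ in range(rnd.randint(1, 50))
        ]
        counts, expected = brute_force_metrics(pairs)
        report = metrics(counts)
        for name, value in expected.items():
            got = getattr(report, name)
            if math.isnan(value):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(value)


class TestPredict:
    def _setting(self):
        cols = {
            "a": ["x"] * 6 + ["y"] * 6,
            "b": ["u", "v"] * 6,
        }
        labels = ["deleterious"] * 6 + ["neutral"] * 6
        ds = make_dataset(cols, labels)
        rules = [
            Rule(literals=(("a", "x"),)),
            Rule(literals=(("b", "u"),)),
        ]
        return ds, RuleSet(rules=rules, schema=ds.schema, config=RunConfig())

    def test_deleterious_iff_any_rule_fires(self):
        ds, rs = self._setting()
        label, firing = predict(rs, {"a": "x", "b": "u"})
        assert label == "deleterious" and len(firing) == 2
        label, firing = predict(rs, {"a": "y", "b": "v"})
        assert label == "neutral" and firing == []
        label, firing = predict(rs, {"a": "y", "b": "u"})
        assert label == "deleterious" and len(firing) == 1

    def test_confusion_over_dataset(self):
        ds, rs = self._setting()
        counts = confusion(rs, ds)
        assert counts.total == len(ds)


class TestTotalPrecision:
    def _reference(self, rule_counts):
        """Dataset where rule i = (f'p{i}', 'hit') has the given (tp, fp)."""
        n_params = len(rule_counts)
        params = [(f"p{i}", ("hit", "miss")) for i in range(n_params)]
        schema = FeatureSchema(params)
        records = []
        k = 0
        for i, (tp, fp) in enumerate(rule_counts):
            for label, count in (("deleterious", tp), ("neutral", fp)):
                for _ in range(count):
                    features = {
                        f"p{j}": ("hit" if j == i else "miss")
                        for j in range(n_params)
                    }
                    records.append(Record(f"r{k}", features, label))
                    k += 1
        return LabeledDataset(schema, records)

    def test_worked_example(self):
        ds = self._reference([(10, 0), (5, 1)])
        rules = [Rule(literals=(("p0", "hit"),)), Rule(literals=(("p1", "hit"),))]
        assert total_precision(rules, ds) == pytest.approx(100 * 15 / 16)

    def test_all_zero_false_positives_gives_100(self):
        ds = self._reference([(4, 0), (3, 0)])
        rules = [Rule(literals=(("p0", "hit"),)), Rule(literals=(("p1", "hit"),))]
        assert total_precision(rules, ds) == pytest.approx(100.0)

    def test_single_rule_equals_its_own_precision(self):
        ds = self._reference([(7, 3)])
        rule = Rule(literals=(("p0", "hit"),))
        tp, fp = rule_confusion(rule, ds)
        assert total_precision([rule], ds) == pytest.approx(100 * tp / (tp + fp))

    def test_empty_rule_list_rejected(self):
        ds = self._reference([(1, 1)])
        with pytest.raises(ValidationError):
            total_precision([], ds)


class TestAssessRules:
    def test_coverage_precision_and_ranking(self):
        cols = {
            "a": ["x"] * 4 + ["z"] * 4 + ["y"] * 8,
            "b": ["u"] * 10 + ["v"] * 6,
        }
        labels = ["deleterious"] * 8 + ["neutral"] * 8
        ds = make_dataset(cols, labels)
        rules = [
            Rule(literals=(("a", "x"),)),  # 4/8 positives, no negatives
            Rule(literals=(("b", "u"),)),  # 8 positives + 2 negatives
        ]
        rs = RuleSet(rules=rules, schema=ds.schema, config=RunConfig())
        assessment = assess_rules(rs, ds)
        by_rule = {s.rule.literals: s for s in assessment.ranked}
        assert by_rule[(("a", "x"),)].coverage_percent == pytest.approx(50.0)
        assert by_rule[(("a", "x"),)].precision_percent == pytest.approx(100.0)
        assert by_rule[(("b", "u"),)].precision_percent == pytest.approx(80.0)
        # 100% precision ranks above 80%
        assert assessment.ranked[0].rule.literals == (("a", "x"),)
        assert assessment.parameter_usage == {"a": 1, "b": 1}

    def test_equal_precision_ranked_by_coverage(self):
        cols = {
            "a": ["x"] * 2 + ["w"] * 6 + ["y"] * 8,
            "b": ["u"] * 8 + ["v"] * 8,
        }
        labels = ["deleterious"] * 8 + ["neutral"] * 8
        ds = make_dataset(cols, labels)
        rules = [
            Rule(literals=(("a", "x"),)),  # coverage 2/8, precision 100
            Rule(literals=(("b", "u"),)),  # coverage 8/8, precision 100
        ]
        rs = RuleSet(rules=rules, schema=ds.schema, config=RunConfig())
        assessment = assess_rules(rs, ds)
        assert assessment.ranked[0].rule.literals == (("b", "u"),)

    def test_multi_rule_table_counts_exact_firing_multiplicity(self):
        cols = {
            "a": ["x", "x", "y", "y"],
            "b": ["u", "v", "u", "v"],
        }
        labels = ["deleterious", "deleterious", "neutral", "neutral"]
        ds = make_dataset(cols, labels)
        rules = [Rule(literals=(("a", "x"),)), Rule(literals=(("b", "u"),))]
        rs = RuleSet(rules=rules, schema=ds.schema, config=RunConfig())
        table = assess_rules(rs, ds).multi_rule_table
        # r0 fires both rules (k=2); r1 fires rule 1 only; r2 fires rule 2 only
        assert table[0] == (1, 1, 1, pytest.approx(50.0))
        assert table[1] == (2, 1, 0, pytest.approx(100.0))


class TestCrossValidate:
    def test_partition_and_fold_sizes(self):
        ds, _ = generate_dataset(default_planted_spec(seed=2, n_pos=50, n_neg=50))
        cv = cross_validate(ds, RunConfig(seed=2, folds=10))
        tested = [i for f in cv.folds for i in f.test_indices]
        assert sorted(tested) == list(range(100))
        assert all(len(f.test_indices) == 10 for f in cv.folds)

    def test_determinism_under_fixed_seed(self):
        ds, _ = generate_dataset(default_planted_spec(seed=4, n_pos=40, n_neg=40))
        a = cross_validate(ds, RunConfig(seed=9, folds=5))
        b = cross_validate(ds, RunConfig(seed=9, folds=5))
        assert a.mean_metrics == b.mean_metrics
        assert [f.test_indices for f in a.folds] == [f.test_indices for f in b.folds]

    def test_separable_data_reaches_high_test_accuracy(self):
        ds, _ = generate_dataset(default_planted_spec(seed=0))
        cv = cross_validate(ds, RunConfig(seed=0, folds=10))
        assert cv.mean_metrics.accuracy >= 0.95
        assert cv.final_ruleset is cv.folds[cv.best_fold].ruleset


class TestChiSquare:
    def test_identical_distributions(self):
        ds = make_dataset(
            {"p": ["a", "b", "a", "b"]},
            ["deleterious", "deleterious", "neutral", "neutral"],
        )
        res = chi_square_compare(ds, "p")
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.significant is False

    def test_hand_computed_contingency(self):
        # [[30,10],[10,30]] without continuity correction:
        # (30*30-10*10)^2 * 80 / 40^4 = 20.0, dof 1
        cols = {"p": ["a"] * 30 + ["b"] * 10 + ["a"] * 10 + ["b"] * 30}
        labels = ["deleterious"] * 40 + ["neutral"] * 40
        ds = make_dataset(cols, labels)
        res = chi_square_compare(ds, "p")
        assert res.chi2 == pytest.approx(20.0)
        assert res.dof == 1
        assert res.significant is True

    def test_constant_parameter_skipped_with_notice(self):
        schema = FeatureSchema([("p", ("a", "b"))])
        ds = make_dataset(
            {"p": ["a", "a", "a", "a"]},
            ["deleterious", "deleterious", "neutral", "neutral"],
            schema=schema,
        )
        res = chi_square_compare(ds, "p")
        assert res.chi2 is None
        assert "skipped" in res.note


class TestAFReliability:
    def test_bin_midpoints(self):
        res = af_reliability(["neutral"] * 10, [0.05 + 0.1 * i for i in range(10)])
        assert res.bin_midpoints == tuple(
            pytest.approx(0.05 + 0.1 * i) for i in range(10)
        )

    def test_all_neutral_has_undefined_r_with_notice(self):
        res = af_reliability(["neutral"] * 20, list(np.linspace(0, 0.99, 20)))
        assert all(p == 0.0 for p, c in zip(res.percent_deleterious, res.bin_counts) if c)
        assert math.isnan(res.pearson_r)
        assert any("undefined" in n for n in res.notes)

    def test_monotone_decreasing_percentages_give_r_minus_one(self):
        # 10 variants per bin; bin i has (90 - 10i)% predicted deleterious
        predictions, freqs = [], []
        for i in range(9):
            n_del = 9 - i
            for j in range(10):
                predictions.append("deleterious" if j < n_del else "neutral")
                freqs.append(0.05 + 0.1 * i)
        res = af_reliability(predictions, freqs)
        assert res.pearson_r == pytest.approx(-1.0)
        assert any("empty bins" in n for n in res.notes)  # bin 10 unoccupied

    def test_frequency_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            af_reliability(["neutral"], [1.2])
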