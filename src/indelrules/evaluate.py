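"""Prediction from rule sets and all downstream statistics.

Includes the 2x2 confusion metrics (accuracy, sensitivity, specificity,
precision, NPV, Matthews correlation coefficient), per-rule coverage and
precision ranking, the multi-rule precision table, combined precision over a
set of firing rules, stratified k-fold cross-validation of the whole
learning pipeline, per-parameter chi-square class comparison, and the
allele-frequency reliability analysis.

A vector is predicted deleterious iff at least one rule covers it; the rules
characterise only the deleterious class, so uncovered vectors default to
neutral.  Undefined ratios (zero denominators) are reported as NaN, never as
silent zeros.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .datamodel import (
    DELETERIOUS,
    NEUTRAL,
    LabeledDataset,
    Record,
    RunConfig,
    ValidationError,
)
from .learner import Rule, RuleSet, covers, learn


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Derived statistics of a confusion matrix; NaN marks an undefined ratio."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    npv: float
    mcc: float

    def to_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "npv": self.npv,
            "mcc": self.mcc,
        }


def _ratio(num: int, den: int) -> float:
    return num / den if den else math.nan


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Standard 2x2 confusion statistics.

    accuracy = (Tp+Tn)/(Tp+Tn+Fp+Fn); sensitivity = Tp/(Tp+Fn);
    specificity = Tn/(Tn+Fp); precision = Tp/(Tp+Fp); NPV = Tn/(Tn+Fn);
    MCC = (Tp·Tn − Fp·Fn) / sqrt((Tp+Fp)(Tp+Fn)(Tn+Fp)(Tn+Fn)).
    """
    if counts.total == 0:
        raise ValidationError("metrics require at least one evaluated record")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else math.nan
    return MetricsReport(
        accuracy=_ratio(tp + tn, counts.total),
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        precision=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        mcc=mcc,
    )


def format_percent(fraction: float) -> str:
    """Render a fraction as a percentage with 2 decimals, half away from zero."""
    if math.isnan(fraction):
        return "NA"
    return str(
        Decimal(repr(fraction * 100)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    )


def predict(
    ruleset: RuleSet, features: Mapping[str, str]
) -> tuple[str, list[Rule]]:
    """Classify one vector: deleterious iff >= 1 rule fires; returns the firing rules."""
    firing = [rule for rule in ruleset.rules if covers(rule, features)]
    return (DELETERIOUS if firing else NEUTRAL, firing)


def confusion(
    ruleset: RuleSet, dataset: LabeledDataset
) -> ConfusionCounts:
    tp = fp = tn = fn = 0
    for rec in dataset.records:
        predicted, _ = predict(ruleset, rec.features)
        if predicted == DELETERIOUS:
            if rec.label == DELETERIOUS:
                tp += 1
            else:
                fp += 1
        else:
            if rec.label == DELETERIOUS:
                fn += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def rule_confusion(rule: Rule, dataset: LabeledDataset) -> tuple[int, int]:
    """(Tp, Fp) of a single rule on a dataset: covered deleterious / neutral."""
    tp = fp = 0
    for rec in dataset.records:
        if covers(rule, rec.features):
            if rec.label == DELETERIOUS:
                tp += 1
            else:
                fp += 1
    return tp, fp


def total_precision(
    firing_rules: Sequence[Rule], reference_dataset: LabeledDataset
) -> float:
    """Combined precision of a set of firing rules, as a percent:
    sum of true positives over sum of (true + false) positives across rules."""
    if not firing_rules:
        raise ValidationError("total_precision requires at least one firing rule")
    tp_sum = denom = 0
    for rule in firing_rules:
        tp, fp = rule_confusion(rule, reference_dataset)
        tp_sum += tp
        denom += tp + fp
    return _ratio(tp_sum, denom) * 100


@dataclass(frozen=True)
class RuleStats:
    rule: Rule
    coverage_percent: float
    precision_percent: float


@dataclass
class RuleAssessment:
    """Per-rule coverage/precision ranking plus the multi-rule precision table.

    ``ranked`` is sorted by precision (desc) then coverage (desc).
    ``multi_rule_table`` rows are (k, deleterious covered by exactly k rules,
    neutral covered by exactly k rules, average precision percent).
    ``parameter_usage`` counts literal occurrences per parameter.
    """

    ranked: list[RuleStats]
    multi_rule_table: list[tuple[int, int, int, float]]
    parameter_usage: dict[str, int]


def parameter_usage(rules: Iterable[Rule]) -> dict[str, int]:
    counter: Counter[str] = Counter()
    for rule in rules:
        counter.update(p for p, _ in rule.literals)
    return dict(counter)


def assess_rules(ruleset: RuleSet, dataset: LabeledDataset) -> RuleAssessment:
    n_pos = len(dataset.positives)
    per_rule = []
    for rule in ruleset.rules:
        tp, fp = rule_confusion(rule, dataset)
        coverage = _ratio(tp, n_pos) * 100 if n_pos else math.nan
        precision = _ratio(tp, tp + fp) * 100
        per_rule.append(RuleStats(rule, coverage, precision))
    ranked = sorted(
        per_rule,
        key=lambda s: (
            -(s.precision_percent if not math.isnan(s.precision_percent) else -1),
            -(s.coverage_percent if not math.isnan(s.coverage_percent) else -1),
        ),
    )
    firing_counts = [
        sum(1 for rule in ruleset.rules if covers(rule, rec.features))
        for rec in dataset.records
    ]
    table = []
    for k in range(1, max(firing_counts, default=0) + 1):
        n_del = sum(
            1
            for rec, c in zip(dataset.records, firing_counts)
            if c == k and rec.label == DELETERIOUS
        )
        n_neut = sum(
            1
            for rec, c in zip(dataset.records, firing_counts)
            if c == k and rec.label != DELETERIOUS
        )
        avg_precision = _ratio(n_del, n_del + n_neut) * 100
        table.append((k, n_del, n_neut, avg_precision))
    return RuleAssessment(
        ranked=ranked,
        multi_rule_table=table,
        parameter_usage=parameter_usage(ruleset.rules),
    )


@dataclass
class FoldResult:
    fold: int
    test_indices: tuple[int, ...]
    ruleset: RuleSet
    test_metrics: MetricsReport
    train_metrics: MetricsReport


@dataclass
class CrossValidationResult:
    folds: list[FoldResult]
    mean_metrics: MetricsReport
    best_fold: int
    final_ruleset: RuleSet


def cross_validate(
    dataset: LabeledDataset,
    config: RunConfig,
    selection: Sequence[str] | None = None,
) -> CrossValidationResult:
    """Stratified k-fold cross-validation of learn + predict.

    Each record lands in the test part exactly once.  Stratification
    preserves the class balance of the full cohort in every fold.  The rule
    set of the best-accuracy fold is retained as the final rule set.
    """
    dataset.two_class()
    seed = config.require_seed()
    labels = [r.label for r in dataset.records]
    splitter = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=seed)
    indices = np.arange(len(dataset.records))
    folds: list[FoldResult] = []
    seen: set[int] = set()
    for fold_no, (train_idx, test_idx) in enumerate(
        splitter.split(indices, labels)
    ):
        if seen & set(test_idx.tolist()):
            raise ValidationError("fold assignment is not a partition")
        seen |= set(test_idx.tolist())
        train = dataset.subset(train_idx.tolist())
        test = dataset.subset(test_idx.tolist())
        if not train.positives or not train.negatives:
            raise ValidationError(
                f"fold {fold_no}: a class is absent from the training split"
            )
        fold_config = config.with_overrides(seed=(seed * 1000003 + fold_no) % 2**31)
        ruleset = learn(train, fold_config, selection)
        folds.append(
            FoldResult(
                fold=fold_no,
                test_indices=tuple(int(i) for i in test_idx),
                ruleset=ruleset,
                test_metrics=metrics(confusion(ruleset, test)),
                train_metrics=metrics(confusion(ruleset, train)),
            )
        )
    if seen != set(range(len(dataset.records))):
        raise ValidationError("fold assignment is not exhaustive")
    mean = MetricsReport(
        **{
            name: float(
                np.nanmean([getattr(f.test_metrics, name) for f in folds])
            )
            for name in (
                "accuracy",
                "sensitivity",
                "specificity",
                "precision",
                "npv",
                "mcc",
            )
        }
    )
    best = max(folds, key=lambda f: f.test_metrics.accuracy)
    return CrossValidationResult(
        folds=folds,
        mean_metrics=mean,
        best_fold=best.fold,
        final_ruleset=best.ruleset,
    )


@dataclass
class ChiSquareResult:
    parameter: str
    chi2: float | None
    dof: int | None
    p_value: float | None
    significant: bool | None
    table: "object"  # pandas DataFrame: value x class counts
    note: str = ""


def chi_square_compare(dataset: LabeledDataset, parameter: str) -> ChiSquareResult:
    """Pearson chi-square (no continuity correction) on the value-by-class
    contingency table of one parameter, at the 95% confidence level."""
    import pandas as pd

    dataset.two_class()
    values = [r.features[parameter] for r in dataset.records]
    labels = [r.label for r in dataset.records]
    table = pd.crosstab(pd.Series(values, name=parameter), pd.Series(labels, name="class"))
    observed = [v for v in dataset.schema.values(parameter) if v in table.index]
    table = table.reindex(observed)
    if len(table.index) < 2:
        return ChiSquareResult(
            parameter, None, None, None, None, table,
            note="parameter is constant; test skipped",
        )
    chi2, p, dof, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return ChiSquareResult(
        parameter, float(chi2), int(dof), float(p), bool(p < 0.05), table
    )


def chi_square_report(dataset: LabeledDataset) -> list[ChiSquareResult]:
    return [chi_square_compare(dataset, p) for p in dataset.schema.names]


@dataclass
class AFReliability:
    """Percent of variants predicted deleterious per allele-frequency bin."""

    bin_edges: tuple[float, ...]
    bin_midpoints: tuple[float, ...]
    bin_counts: tuple[int, ...]
    percent_deleterious: tuple[float, ...]  # NaN for empty bins
    pearson_r: float  # NaN when undefined
    notes: list[str] = field(default_factory=list)


def af_reliability(
    predictions: Sequence[str], allele_frequencies: Sequence[float]
) -> AFReliability:
    """Group variants into allele-frequency bins of width 0.1 and correlate
    the bin midpoint with the percent predicted deleterious (Pearson r).

    Under the population-genetics expectation that truly deleterious variants
    segregate at low frequency, a reliable predictor shows a negative r.
    """
    if len(predictions) != len(allele_frequencies):
        raise ValidationError("predictions and frequencies differ in length")
    for f in allele_frequencies:
        if not 0.0 <= f <= 1.0:
            raise ValidationError(f"allele frequency {f} outside [0, 1]")
    edges = tuple(round(0.1 * i, 1) for i in range(11))
    midpoints = tuple(round(0.05 + 0.1 * i, 2) for i in range(10))
    counts = [0] * 10
    deleterious = [0] * 10
    for pred, freq in zip(predictions, allele_frequencies):
        b = min(int(freq / 0.1), 9)
        counts[b] += 1
        if pred == DELETERIOUS:
            deleterious[b] += 1
    percents = [
        (100.0 * d / c) if c else math.nan for d, c in zip(deleterious, counts)
    ]
    notes = []
    xs = [m for m, c in zip(midpoints, counts) if c]
    ys = [p for p, c in zip(percents, counts) if c]
    if len(xs) < len(midpoints):
        notes.append(
            f"{len(midpoints) - len(xs)} empty bins excluded from the correlation"
        )
    if len(xs) < 2 or len(set(ys)) < 2 or len(set(xs)) < 2:
        r = math.nan
        notes.append("Pearson r undefined (fewer than two varying bins)")
    else:
        r = float(stats.pearsonr(xs, ys).statistic)
    return AFReliability(
        bin_edges=edges,
        bin_midpoints=midpoints,
        bin_counts=tuple(counts),
        percent_deleterious=tuple(percents),
        pearson_r=r,
        notes=notes,
    )
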