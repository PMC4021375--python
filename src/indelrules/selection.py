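"""Parameter selection: discriminative power, association filtering, wrapper grid.

The discriminative power of a categorical parameter is
x = sum_i |fn_i − fp_i|, where fn_i / fp_i are the within-class relative
frequencies of value i among negative / positive examples.  x lies in
[0, 2]: 0 for identical class distributions, 2 for perfectly separating
parameters.  Values absent from a class contribute with frequency 0 (no
smoothing).

Pairwise "correlation" between categorical parameters is measured as
bias-uncorrected Cramér's V.  Selection is a greedy pass in descending x
(ties broken by schema order): keep the parameter, drop every
not-yet-processed parameter associated with it at or above the cutoff, and
finally drop kept parameters whose x falls below the x cutoff.  A wrapper
grid re-runs selection plus cross-validated rule learning over a grid of
cutoffs to pick the pair that maximises CV accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import LabeledDataset, RunConfig, ValidationError
from .evaluate import cross_validate

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiscriminativePower:
    parameter_name: str
    x: float

    def __post_init__(self):
        if not 0.0 <= self.x <= 2.0 + 1e-12:
            raise ValidationError(f"x = {self.x} outside [0, 2]")


def discriminative_power(
    dataset: LabeledDataset, parameter: str
) -> DiscriminativePower:
    dataset.two_class()
    pos = dataset.positives
    neg = dataset.negatives
    if not pos or not neg:
        raise ValidationError("discriminative power requires both classes non-empty")
    values = dataset.schema.values(parameter)
    x = 0.0
    for value in values:
        fp = sum(1 for r in pos if r.features[parameter] == value) / len(pos)
        fn = sum(1 for r in neg if r.features[parameter] == value) / len(neg)
        x += abs(fn - fp)
    return DiscriminativePower(parameter_name=parameter, x=x)


def cramers_v(a: Sequence[str], b: Sequence[str]) -> float:
    """Bias-uncorrected Cramér's V between two categorical vectors.

    Defined as 0 (with a warning) when either vector is constant.
    """
    table = pd.crosstab(pd.Series(list(a)), pd.Series(list(b))).to_numpy()
    r, c = table.shape
    if r < 2 or c < 2:
        log.warning("constant parameter in association; V defined as 0")
        return 0.0
    chi2 = stats.chi2_contingency(table, correction=False)[0]
    n = table.sum()
    return float(np.sqrt(chi2 / (n * (min(r, c) - 1))))


def association_matrix(dataset: LabeledDataset) -> pd.DataFrame:
    """Symmetric matrix of pairwise Cramér's V over all schema parameters."""
    names = dataset.schema.names
    if len(names) < 2:
        raise ValidationError("association matrix requires >= 2 parameters")
    columns = {p: [r.features[p] for r in dataset.records] for p in names}
    matrix = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for a, b in combinations(names, 2):
        v = cramers_v(columns[a], columns[b])
        matrix.loc[a, b] = v
        matrix.loc[b, a] = v
    return matrix


@dataclass
class SelectionResult:
    """Outcome of the two-stage filter.

    ``kept`` (ordered by descending x), ``dropped_correlated`` as
    (dropped, kept_partner, association), ``dropped_low_x``, the full
    association matrix, and the per-parameter x values.
    """

    kept: list[str]
    dropped_correlated: list[tuple[str, str, float]]
    dropped_low_x: list[str]
    correlation_matrix: pd.DataFrame
    x_values: dict[str, float]


def select_parameters(
    dataset: LabeledDataset,
    correlation_cutoff: float,
    x_cutoff: float,
) -> SelectionResult:
    if not 0.0 <= correlation_cutoff <= 1.0:
        raise ValidationError("correlation_cutoff must lie in [0, 1]")
    if x_cutoff < 0:
        raise ValidationError("x_cutoff must be non-negative")
    names = dataset.schema.names
    x_values = {p: discriminative_power(dataset, p).x for p in names}
    matrix = association_matrix(dataset)
    # descending x; ties broken by schema order
    order = sorted(names, key=lambda p: (-x_values[p], dataset.schema.index(p)))
    dropped: dict[str, tuple[str, float]] = {}
    kept: list[str] = []
    for p in order:
        if p in dropped:
            continue
        kept.append(p)
        for q in order:
            if q == p or q in dropped or q in kept:
                continue
            v = float(matrix.loc[p, q])
            if v >= correlation_cutoff:
                dropped[q] = (p, v)
    dropped_low_x = [p for p in kept if x_values[p] < x_cutoff]
    kept = [p for p in kept if x_values[p] >= x_cutoff]
    return SelectionResult(
        kept=kept,
        dropped_correlated=[(q, p, v) for q, (p, v) in dropped.items()],
        dropped_low_x=dropped_low_x,
        correlation_matrix=matrix,
        x_values=x_values,
    )


def wrapper_grid(
    dataset: LabeledDataset,
    correlation_cutoffs: Sequence[float],
    x_cutoffs: Sequence[float],
    config: RunConfig,
) -> pd.DataFrame:
    """Evaluate every (correlation cutoff, x cutoff) cell by cross-validated
    learning on the selected parameter subset.

    Returns one row per cell with the parameter count and the mean train/test
    accuracy — the train-vs-test curve doubles as an over-fitting diagnostic.
    """
    config.require_seed()
    rows = []
    for cc in correlation_cutoffs:
        for xc in x_cutoffs:
            selection = select_parameters(dataset, cc, xc)
            if not selection.kept:
                rows.append(
                    {
                        "correlation_cutoff": cc,
                        "x_cutoff": xc,
                        "n_parameters": 0,
                        "cv_accuracy": np.nan,
                        "train_accuracy": np.nan,
                    }
                )
                continue
            cv = cross_validate(dataset, config, selection.kept)
            rows.append(
                {
                    "correlation_cutoff": cc,
                    "x_cutoff": xc,
                    "n_parameters": len(selection.kept),
                    "cv_accuracy": cv.mean_metrics.accuracy,
                    "train_accuracy": float(
                        np.nanmean([f.train_metrics.accuracy for f in cv.folds])
                    ),
                }
            )
    return pd.DataFrame(rows)
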