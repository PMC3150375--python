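"""Replicate aggregation and the study's hypothesis test.

The experimental unit hierarchy is image → chamber → condition → independent
experiment: per-image area fractions are averaged within each chamber,
chamber means are averaged within a condition for each experiment, and the
reported statistic is the across-experiment mean ± sample s.d. (n−1).
Conditions are compared with an unpaired two-tailed Student's t-test
assuming equal variances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ..transport import InvalidParameterError


@dataclass(frozen=True)
class ConditionSummary:
    condition: str
    chamber_means: dict
    per_experiment_means: dict
    mean: float
    sd: float
    n_experiments: int
    fold_increase: float | None = None


def aggregate_condition(measurements: pd.DataFrame, condition: str,
                        baseline: float | None = None) -> ConditionSummary:
    """Aggregate per-image area fractions into a condition summary.

    ``measurements`` needs columns ``condition``, ``experiment``, ``chamber``
    and ``value`` (one row per image). If ``baseline`` is given, the summary
    also reports the fold increase mean/baseline.
    """
    required = {"condition", "experiment", "chamber", "value"}
    missing = required - set(measurements.columns)
    if missing:
        raise InvalidParameterError(f"measurements missing columns: {sorted(missing)}")
    df = measurements[measurements["condition"] == condition]
    if df.empty:
        raise InvalidParameterError(f"no measurements for condition {condition!r}")
    chamber_means = (
        df.groupby(["experiment", "chamber"])["value"].mean()
    )
    per_exp = chamber_means.groupby("experiment").mean()
    mean = float(per_exp.mean())
    sd = float(per_exp.std(ddof=1)) if len(per_exp) > 1 else 0.0
    fold = None
    if baseline is not None:
        if baseline <= 0:
            raise InvalidParameterError("baseline must be > 0")
        fold = mean / baseline
    return ConditionSummary(
        condition=condition,
        chamber_means=chamber_means.to_dict(),
        per_experiment_means=per_exp.to_dict(),
        mean=mean,
        sd=sd,
        n_experiments=len(per_exp),
        fold_increase=fold,
    )


def ttest_unpaired_equal_var(group_a, group_b) -> tuple[float, float]:
    """Unpaired two-tailed Student's t-test with pooled (equal) variance.

    Returns ``(t, p)`` with ``n_a + n_b - 2`` degrees of freedom. Degenerate
    zero-variance inputs: equal means give p = 1; unequal means give p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidParameterError("each group needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
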