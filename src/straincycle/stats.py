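"""Statistical layer: condition summaries, Holm-Sidak t-tests, KS tests.

Replicate unit is the independent experiment (one simulation seed or one
imaging run).  Percent-positive metrics are compared between conditions with
two-sided unpaired t-tests and the Holm-Sidak step-down adjustment; distance
or intensity distributions, where normality is not assumed, are compared with
the two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "holm_sidak_ttests",
    "ks_compare",
    "condition_summary",
]


@dataclass
class ComparisonResult:
    test: str  # "t" or "KS"
    table: pd.DataFrame  # metric, group_a, group_b, n_a, n_b, mean_a, mean_b, sem_a, sem_b, statistic, p_raw, p_adjusted
    excluded: list[str] = field(default_factory=list)


def _sem(x: np.ndarray) -> float:
    return float(sps.sem(x, ddof=1)) if len(x) > 1 else np.nan


def holm_sidak_ttests(
    comparisons: dict[str, tuple[Sequence[float], Sequence[float]]],
    equal_var: bool = False,
    group_labels: Optional[dict[str, tuple[str, str]]] = None,
) -> ComparisonResult:
    """Unpaired two-sided t-tests with Holm-Sidak step-down correction.

    ``comparisons`` maps a metric/comparison name to the two replicate
    samples.  The default is the Welch (unequal-variance) t-test; set
    ``equal_var=True`` for the pooled-variance form.  Comparisons with fewer
    than two observations in either group are flagged and excluded from the
    adjustment family.  The step-down adjustment sorts raw p ascending and
    sets ``p_adj_(i) = 1 - (1 - p_(i))^(m - i + 1)`` with a running maximum.
    """
    rows = []
    excluded = []
    names = []
    raw_ps = []
    for name, (a, b) in comparisons.items():
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        labels = (group_labels or {}).get(name, ("a", "b"))
        if len(a) < 2 or len(b) < 2:
            excluded.append(name)
            continue
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        names.append(name)
        raw_ps.append(float(res.pvalue))
        rows.append(
            {
                "metric": name,
                "group_a": labels[0],
                "group_b": labels[1],
                "n_a": len(a),
                "n_b": len(b),
                "mean_a": float(a.mean()),
                "mean_b": float(b.mean()),
                "sem_a": _sem(a),
                "sem_b": _sem(b),
                "statistic": float(res.statistic),
                "p_raw": float(res.pvalue),
            }
        )
    if raw_ps:
        _, p_adj, _, _ = multipletests(raw_ps, method="holm-sidak")
        for row, p in zip(rows, p_adj):
            row["p_adjusted"] = float(p)
    table = pd.DataFrame(
        rows,
        columns=[
            "metric", "group_a", "group_b", "n_a", "n_b", "mean_a", "mean_b",
            "sem_a", "sem_b", "statistic", "p_raw", "p_adjusted",
        ],
    )
    return ComparisonResult(test="t", table=table, excluded=excluded)


def ks_compare(
    sample_a: Sequence[float], sample_b: Sequence[float], metric: str = "metric"
) -> ComparisonResult:
    """Two-sample Kolmogorov-Smirnov test, D = sup |ECDF_a - ECDF_b|.

    Uses the asymptotic p-value; the statistic itself is the quantity of
    interest for distribution-valued metrics.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("KS test requires non-empty samples")
    res = sps.ks_2samp(a, b, method="asymp")
    table = pd.DataFrame(
        [
            {
                "metric": metric,
                "group_a": "a",
                "group_b": "b",
                "n_a": len(a),
                "n_b": len(b),
                "mean_a": float(a.mean()),
                "mean_b": float(b.mean()),
                "sem_a": _sem(a),
                "sem_b": _sem(b),
                "statistic": float(res.statistic),
                "p_raw": float(res.pvalue),
                "p_adjusted": float(res.pvalue),
            }
        ]
    )
    return ComparisonResult(test="KS", table=table)


def condition_summary(replicates: dict[str, Sequence[float]]) -> pd.DataFrame:
    """Mean +/- SEM per condition; SEM is NaN-flagged for n = 1."""
    if not replicates:
        raise ValueError("no conditions given")
    rows = []
    for name, values in replicates.items():
        v = np.asarray(values, dtype=float)
        if len(v) == 0:
            raise ValueError(f"condition {name!r} has no replicates")
        rows.append(
            {
                "condition": name,
                "n": len(v),
                "mean": float(v.mean()),
                "sem": _sem(v),
                "sem_undefined": len(v) < 2,
            }
        )
    return pd.DataFrame(rows)
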