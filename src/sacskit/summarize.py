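"""Group-level response tables and parameter-dependence regressions.

Per stimulation condition (frequency × amplitude), neurons passing the
sparse-rate filter are classified from their permutation-test results into
response categories (any change, √|PPC| increase/decrease, FR
increase/decrease); per-subject percentages are then summarized across
subjects by the median with a binomial order-statistic confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ResponseTable", "classify_and_tabulate", "ols_slope", "median_ci"]

CATEGORIES = [
    "any_change",
    "ppc_increase",
    "ppc_decrease",
    "fr_increase",
    "fr_decrease",
]


def median_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """Median with a distribution-free (binomial order-statistic) CI.

    The interval is formed from the order statistics (x_(lo), x_(hi)) whose
    binomial coverage of the median reaches the requested level; when the
    sample is too small for that coverage, the widest order statistics (the
    sample extremes) are returned.  Returns (median, lower, upper); an empty
    sample yields NaNs.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        return (np.nan, np.nan, np.nan)
    med = float(np.median(x))
    if n == 1:
        return (med, x[0], x[0])
    alpha = 1.0 - level
    lo = int(stats.binom.ppf(alpha / 2.0, n, 0.5))
    hi = int(stats.binom.isf(alpha / 2.0, n, 0.5))
    # widen by one if the achieved coverage falls short
    while (stats.binom.cdf(hi, n, 0.5) - stats.binom.cdf(lo - 1, n, 0.5)) < level and (
        lo > 0 or hi < n - 1
    ):
        if lo > 0:
            lo -= 1
        if hi < n - 1:
            hi += 1
    lo = max(lo, 0)
    hi = min(hi, n - 1)
    return (med, float(x[lo]), float(x[hi]))


def ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope with a t-test p-value on n − 2 degrees of freedom.

    Returns (slope, intercept, p).  Requires n ≥ 3 and non-constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("regression requires at least 3 points")
    if np.all(x == x[0]):
        raise ValueError("regression requires non-constant x")
    res = stats.linregress(x, y)
    return (float(res.slope), float(res.intercept), float(res.pvalue))


@dataclass
class ResponseTable:
    """Per-condition response percentages and effect magnitudes.

    ``percentages``: (frequency, amplitude, category) → median and 95% CI of
    the per-subject percentage of eligible neurons in that category.
    ``magnitudes``: median and CI of the effect size (Δ√|PPC| or ΔFR, Hz)
    among neurons significant in that category.
    """

    percentages: pd.DataFrame
    magnitudes: pd.DataFrame


def _categorize(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["ppc_increase"] = out["ppc_significant"] & (out["ppc_direction"] == "increase")
    out["ppc_decrease"] = out["ppc_significant"] & (out["ppc_direction"] == "decrease")
    out["fr_increase"] = out["fr_significant"] & (out["fr_direction"] == "increase")
    out["fr_decrease"] = out["fr_significant"] & (out["fr_direction"] == "decrease")
    out["any_change"] = out["fr_significant"] | out["ppc_significant"]
    return out


def classify_and_tabulate(results: pd.DataFrame) -> ResponseTable:
    """Build the response table from per-neuron, per-trial test results.

    ``results`` is a tidy table with one row per (subject, neuron, trial)
    holding columns: subject, neuron_id, frequency, amplitude,
    fr_significant, fr_direction, delta_fr, ppc_significant, ppc_direction,
    delta_ppc.  Only neurons passing the sparse-rate filter should be
    present.  Conditions with no eligible neurons are marked empty (NaN).
    """
    required = {
        "subject", "neuron_id", "frequency", "amplitude",
        "fr_significant", "fr_direction", "delta_fr",
        "ppc_significant", "ppc_direction", "delta_ppc",
    }
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = _categorize(results)

    pct_rows = []
    mag_rows = []
    for (freq, amp), cell in df.groupby(["frequency", "amplitude"]):
        for cat in CATEGORIES:
            per_subject = (
                cell.groupby("subject")[cat].mean().to_numpy() * 100.0
            )
            med, lo, hi = median_ci(per_subject)
            pct_rows.append(
                {
                    "frequency": freq,
                    "amplitude": amp,
                    "category": cat,
                    "median_pct": med,
                    "ci_lower": lo,
                    "ci_upper": hi,
                    "n_subjects": per_subject.size,
                }
            )
        for cat, col in [
            ("ppc_increase", "delta_ppc"),
            ("ppc_decrease", "delta_ppc"),
            ("fr_increase", "delta_fr"),
            ("fr_decrease", "delta_fr"),
        ]:
            vals = cell.loc[cell[cat], col].to_numpy()
            med, lo, hi = median_ci(vals) if vals.size else (np.nan, np.nan, np.nan)
            mag_rows.append(
                {
                    "frequency": freq,
                    "amplitude": amp,
                    "category": cat,
                    "median_effect": med,
                    "ci_lower": lo,
                    "ci_upper": hi,
                    "n_neurons": vals.size,
                }
            )
    return ResponseTable(
        percentages=pd.DataFrame(pct_rows), magnitudes=pd.DataFrame(mag_rows)
    )
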