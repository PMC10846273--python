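"""Frequency estimation and group comparison for colony-count assays.

Resistant colonies count cheaters, so the cooperator frequency estimate
from a plate of n colonies with k resistant ones is p_hat = 1 - k/n, with
a 95% Wilson score interval (well-behaved at the 0/1 boundaries that a
fixed or swept population actually reaches; the Wald interval is not).

Group comparisons are classical Student t-tests on per-line frequencies —
pooled-variance unpaired by default, paired and Welch variants behind
flags — reported two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "FrequencyEstimate",
    "GroupComparison",
    "wilson_interval",
    "estimate_frequency",
    "add_frequency_estimates",
    "summarize_lines",
    "compare_groups",
    "write_summary_tsv",
    "write_comparison_tsv",
]


@dataclass(frozen=True)
class FrequencyEstimate:
    """Estimated cooperator frequency with a 95% confidence interval."""

    p_hat: float
    ci_low: float
    ci_high: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.p_hat <= self.ci_high <= 1.0):
            raise ValueError(f"interval must satisfy 0 <= low <= p_hat <= high <= 1: {self}")


@dataclass(frozen=True)
class GroupComparison:
    """Two-sided t-test result."""

    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    mean_difference: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value must be in [0, 1], got {self.p_value}")


def wilson_interval(n_success, n, conf: float = 0.95):
    """Wilson score interval for a binomial proportion (vectorized)."""
    low, high = proportion_confint(n_success, n, alpha=1.0 - conf, method="wilson")
    return low, high


def estimate_frequency(n_resistant: int, n_colonies: int) -> FrequencyEstimate:
    """Cooperator frequency from plated colony counts.

    Resistant colonies are cheaters; the cooperator count is
    n_colonies - n_resistant and the 95% Wilson interval is taken on the
    cooperator proportion.
    """
    if n_colonies < 1:
        raise ValueError(f"n_colonies must be >= 1, got {n_colonies}")
    if not (0 <= n_resistant <= n_colonies):
        raise ValueError("need 0 <= n_resistant <= n_colonies")
    n_coop = n_colonies - n_resistant
    low, high = wilson_interval(n_coop, n_colonies)
    return FrequencyEstimate(
        p_hat=n_coop / n_colonies,
        ci_low=float(low),
        ci_high=float(high),
        n=n_colonies,
    )


def add_frequency_estimates(records: pd.DataFrame) -> pd.DataFrame:
    """Append p_hat / ci_low / ci_high columns to a record table."""
    if records.empty:
        raise ValueError("record table is empty")
    out = records.copy()
    n_coop = out["n_colonies"] - out["n_resistant"]
    out["p_hat"] = n_coop / out["n_colonies"]
    low, high = wilson_interval(n_coop.to_numpy(), out["n_colonies"].to_numpy())
    out["ci_low"] = low
    out["ci_high"] = high
    return out


def summarize_lines(records: pd.DataFrame) -> pd.DataFrame:
    """Across-line mean and dispersion of estimated frequency per generation.

    Returns one row per generation with columns generation, mean_p, sd_p
    (sample SD; 0 for a single line) and n_lines.
    """
    est = add_frequency_estimates(records)
    grouped = est.groupby("generation")["p_hat"]
    out = pd.DataFrame({
        "mean_p": grouped.mean(),
        "sd_p": grouped.std(ddof=1).fillna(0.0),
        "n_lines": grouped.size(),
    }).reset_index()
    return out.sort_values("generation", ignore_index=True)


def compare_groups(
    group_a,
    group_b,
    paired: bool = False,
    welch: bool = False,
) -> GroupComparison:
    """Two-sided Student t-test between two sets of frequencies.

    Unpaired pooled-variance by default; ``paired`` switches to the paired
    test (equal lengths required) and ``welch`` to the unequal-variance
    unpaired test.  Two groups with zero variance and equal means compare
    as t = 0, p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if paired and welch:
        raise ValueError("paired and welch are mutually exclusive")
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    with warnings.catch_warnings():
        # identical groups trip scipy's catastrophic-cancellation warning;
        # that degenerate case is handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        if paired:
            if a.size != b.size:
                raise ValueError("paired test requires equal group lengths")
            res = stats.ttest_rel(a, b)
        else:
            res = stats.ttest_ind(a, b, equal_var=not welch)
    t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    if np.isnan(t):  # degenerate: no variance anywhere
        if np.isclose(a.mean(), b.mean()):
            t, p = 0.0, 1.0
        else:
            t = math_inf_sign(a.mean() - b.mean())
            p = 0.0
    return GroupComparison(
        t_statistic=t,
        degrees_of_freedom=df,
        p_value=p,
        mean_difference=float(a.mean() - b.mean()),
    )


def math_inf_sign(diff: float) -> float:
    return float(np.inf if diff > 0 else -np.inf)


def write_summary_tsv(summary: pd.DataFrame, path) -> None:
    """Write a per-generation summary TSV (generation, mean_p, sd_p, n_lines)."""
    summary.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_comparison_tsv(comparison: GroupComparison, path) -> None:
    """Write a t-test report TSV with columns t, df, p, mean_diff."""
    with open(path, "w") as fh:
        fh.write("t\tdf\tp\tmean_diff\n")
        fh.write(
            f"{comparison.t_statistic:.17g}\t{comparison.degrees_of_freedom:.17g}\t"
            f"{comparison.p_value:.17g}\t{comparison.mean_difference:.17g}\n"
        )
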