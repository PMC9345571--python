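"""Performance metrics and table assembly for the estimator comparison.

Estimates are compared to the known population size by root mean-squared
error, bias, and the coverage of nominal-0.95 uncertainty intervals.
Effectively infinite estimates (unbounded loglinear fits) are kept in
the computations and rendered with the ``> 10^9`` sentinel convention;
failed estimates count as non-covering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OVERFLOW_THRESHOLD",
    "EstimateResult",
    "PerformanceSummary",
    "rmse",
    "bias",
    "coverage",
    "match_table",
    "aggregate_tables",
    "render_value",
    "results_to_frame",
    "write_results",
    "read_results",
]

#: Estimates (or summary magnitudes) beyond this are rendered as "> 10^9".
OVERFLOW_THRESHOLD = 1e9


@dataclass(frozen=True)
class EstimateResult:
    """One estimate of N from one method on one (truncated) sample."""

    method: str  # LLM-AIC | LLM-BMA | BLCM
    replicate: int
    pattern: str
    mean_p: float
    N: int
    K_use: int
    N_hat: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    selected_model: str | None = None
    failed: bool = False

    def __post_init__(self) -> None:
        if not self.failed and not self.N_hat >= 0:
            raise ValueError("a successful estimate must be nonnegative")


@dataclass(frozen=True)
class PerformanceSummary:
    """Aggregated performance for one design cell and method."""

    N: int
    mean_p: float
    K_use: int
    method: str
    rmse: float
    bias: float
    coverage: float
    m: int


def rmse(estimates: Sequence[float], true_N: int) -> float:
    """Root mean-squared error; non-finite estimates propagate to inf."""
    e = np.asarray(estimates, dtype=float)
    if e.size == 0:
        raise ValueError("no estimates")
    with np.errstate(over="ignore", invalid="ignore"):
        return float(np.sqrt(np.mean((e - true_N) ** 2)))


def bias(estimates: Sequence[float], true_N: int) -> float:
    """Mean estimate minus the true size."""
    e = np.asarray(estimates, dtype=float)
    if e.size == 0:
        raise ValueError("no estimates")
    return float(np.mean(e) - true_N)


def coverage(intervals: Iterable[tuple[float, float]], true_N: int) -> float:
    """Fraction of intervals containing the truth; NaN bounds never cover."""
    hits, m = 0, 0
    for lo, hi in intervals:
        m += 1
        if np.isfinite(lo) and lo <= true_N and true_N <= hi:
            hits += 1
    if m == 0:
        raise ValueError("no intervals")
    return hits / m


def render_value(x: float, threshold: float = OVERFLOW_THRESHOLD) -> str:
    """Table rendering with the overflow sentinel convention."""
    if np.isnan(x) or x > threshold:
        return "> 10^9"
    if x < -threshold:
        return "< -10^9"
    return f"{x:,.0f}"


def match_table(selections: Sequence[tuple[str, str]]) -> tuple[pd.Series, pd.DataFrame]:
    """Model-matching percentages of AIC selection.

    ``selections`` holds (generating pattern, selected label) pairs.
    Returns the per-pattern percentage of correct matches and the full
    cross-tabulation of percentages by generating pattern.
    """
    df = pd.DataFrame(selections, columns=["generated", "selected"])
    allowed = {"Mb", "Mbh", "Mh", "Mth", "Mt"}
    bad = set(df["generated"]) - allowed
    if bad:
        raise ValueError(f"matching is defined for loglinear-generating patterns only, got {bad}")
    cross = pd.crosstab(df["generated"], df["selected"], normalize="index") * 100
    correct = pd.Series(
        {g: cross.loc[g, g] if g in cross.columns else 0.0 for g in cross.index},
        name="percent_correct",
    )
    return correct, cross


def results_to_frame(results: Iterable[EstimateResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def write_results(results: Iterable[EstimateResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def aggregate_tables(
    results: pd.DataFrame | Iterable[EstimateResult],
    threshold: float = OVERFLOW_THRESHOLD,
) -> tuple[list[PerformanceSummary], pd.DataFrame]:
    """Pool patterns within each (N, mean_p, K_use, method) design cell.

    Returns the numeric summaries and a rendered table (RMSE, bias,
    coverage, relative RMSE) using the overflow sentinel convention.
    Failed estimates enter RMSE/bias as non-finite values and never
    cover.
    """
    df = results if isinstance(results, pd.DataFrame) else results_to_frame(results)
    if df.empty:
        raise ValueError("no results to aggregate")
    summaries: list[PerformanceSummary] = []
    rows = []
    for (N, mean_p, K_use, method), g in df.groupby(["N", "mean_p", "K_use", "method"]):
        est = np.where(g["failed"].to_numpy(dtype=bool), np.inf, g["N_hat"].to_numpy(dtype=float))
        ivals = list(zip(g["ci_low"].to_numpy(dtype=float), g["ci_high"].to_numpy(dtype=float)))
        s = PerformanceSummary(
            N=int(N),
            mean_p=float(mean_p),
            K_use=int(K_use),
            method=str(method),
            rmse=rmse(est, int(N)),
            bias=bias(est, int(N)),
            coverage=coverage(ivals, int(N)),
            m=len(g),
        )
        summaries.append(s)
        rows.append(
            {
                "N": s.N,
                "mean_p": s.mean_p,
                "K_use": s.K_use,
                "method": s.method,
                "m": s.m,
                "rmse": render_value(s.rmse, threshold),
                "bias": render_value(s.bias, threshold),
                "coverage": f"{s.coverage:.3f}",
                "relative_rmse": (
                    f"{s.rmse / s.N:.3f}" if np.isfinite(s.rmse) and s.rmse <= threshold else "> 10^9"
                ),
            }
        )
    table = pd.DataFrame(rows).sort_values(["N", "mean_p", "K_use", "method"]).reset_index(drop=True)
    return summaries, table
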