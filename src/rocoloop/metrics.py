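"""Prediction-accuracy statistics for predicted vs measured concentrations.

Performance error uses the Varvel convention with the prediction in the
denominator,

    PE = 100 · (measured − predicted) / predicted  [%]

summarised per condition by its median (MDPE, bias) and the median of its
absolute value (MDAPE, inaccuracy).  Agreement plots are characterised by
the through-origin least-squares slope Σxy/Σx² (exact for y = c·x) and
the ordinary product-moment correlation.  Summary statistics report the
sample mean, SD (n−1) and a 95 % interval whose convention — Student-t
interval for the mean, or a mean ± 1.96·SD population range — is an
explicit, recorded choice.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "performance_error",
    "mdpe",
    "mdape",
    "origin_slope",
    "pearson_r",
    "summarize",
    "evaluate_records",
]


def performance_error(measured: float, predicted: float) -> float:
    """Varvel performance error in percent; requires predicted > 0."""
    if predicted <= 0 or not math.isfinite(predicted):
        raise ValueError(f"predicted must be > 0, got {predicted}")
    if measured < 0 or not math.isfinite(measured):
        raise ValueError(f"measured must be finite and >= 0, got {measured}")
    return 100.0 * (measured - predicted) / predicted


def _as_nonempty(values: Iterable[float]) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("empty performance-error set")
    return arr


def mdpe(pe_set: Iterable[float]) -> float:
    """Median performance error (%): the bias of the prediction."""
    return float(np.median(_as_nonempty(pe_set)))


def mdape(pe_set: Iterable[float]) -> float:
    """Median absolute performance error (%): the inaccuracy."""
    return float(np.median(np.abs(_as_nonempty(pe_set))))


def origin_slope(x: Sequence[float], y: Sequence[float]) -> float:
    """Least-squares slope of the through-origin regression y = b·x."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.size < 2:
        raise ValueError("x and y must have equal length >= 2")
    sxx = float(xa @ xa)
    if sxx == 0.0:
        raise ValueError("all x are zero: through-origin slope undefined")
    return float(xa @ ya) / sxx


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(xa, ya).statistic)


def summarize(values: Sequence[float], ci_method: str = "t") -> dict[str, float | str]:
    """Mean, SD (n−1) and 95 % interval of a sample.

    ``ci_method`` selects the interval convention: ``"t"`` is the Student-t
    confidence interval for the mean; ``"normal_2sd"`` is the mean ± 1.96·SD
    population range.  The convention used is echoed in the result so that
    downstream tables are self-describing.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("summarize requires n >= 2")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if ci_method == "t":
        half = float(stats.t.ppf(0.975, arr.size - 1)) * sd / math.sqrt(arr.size)
    elif ci_method == "normal_2sd":
        half = 1.959963984540054 * sd
    else:
        raise ValueError(f"unknown ci_method: {ci_method!r}")
    return {
        "n": int(arr.size),
        "mean": mean,
        "sd": sd,
        "ci95_low": mean - half,
        "ci95_high": mean + half,
        "ci_method": ci_method,
    }


def evaluate_records(records: pd.DataFrame, ci_method: str = "t") -> pd.DataFrame:
    """Per-condition accuracy table from a sampling-record frame.

    Expects columns ``condition``, ``predicted_cp_ug_ml`` and
    ``measured_cp_ug_ml``; returns one row per condition with summary
    statistics of both concentrations, MDPE, MDAPE, through-origin slope
    and correlation (the layout of a clinical agreement report).  An empty
    input yields an empty, correctly-typed table.
    """
    columns = [
        "condition", "n",
        "mean_predicted", "sd_predicted", "ci95_low_predicted", "ci95_high_predicted",
        "mean_measured", "sd_measured", "ci95_low_measured", "ci95_high_measured",
        "mdpe_pct", "mdape_pct", "origin_slope", "pearson_r", "ci_method",
    ]
    rows = []
    if len(records) > 0:
        for condition, grp in records.groupby("condition", sort=True):
            pred = grp["predicted_cp_ug_ml"].to_numpy(dtype=float)
            meas = grp["measured_cp_ug_ml"].to_numpy(dtype=float)
            pe = [performance_error(m, p) for m, p in zip(meas, pred) if p > 0]
            row: dict[str, object] = {"condition": condition, "n": len(grp)}
            if len(grp) >= 2:
                sp = summarize(pred, ci_method)
                sm = summarize(meas, ci_method)
                row.update({
                    "mean_predicted": sp["mean"], "sd_predicted": sp["sd"],
                    "ci95_low_predicted": sp["ci95_low"],
                    "ci95_high_predicted": sp["ci95_high"],
                    "mean_measured": sm["mean"], "sd_measured": sm["sd"],
                    "ci95_low_measured": sm["ci95_low"],
                    "ci95_high_measured": sm["ci95_high"],
                })
                row["origin_slope"] = origin_slope(pred, meas)
            else:
                row["mean_predicted"] = float(pred.mean())
                row["mean_measured"] = float(meas.mean())
            if pe:
                row["mdpe_pct"] = mdpe(pe)
                row["mdape_pct"] = mdape(pe)
            if len(grp) >= 3 and np.ptp(pred) > 0 and np.ptp(meas) > 0:
                row["pearson_r"] = pearson_r(pred, meas)
            row["ci_method"] = ci_method
            rows.append(row)
    return pd.DataFrame(rows, columns=columns)
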