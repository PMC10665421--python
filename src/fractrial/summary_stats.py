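"""Descriptive statistics of invariant fields and the correlation battery.

Per avatar, landmark and region, each invariant field is condensed to six
descriptive statistics (mean, median, IQR, MAD, P90, P95).  The avatar-level
median then enters a Pearson correlation battery against the four
anthropometric parameters (weight, height, BMI, tibia length), one row per
parameter x landmark x region x invariant — 4 x 5 x 2 x 4 = 160 rows with
the default pipeline.

Conventions pinned for testability: quantiles use linear interpolation
between order statistics (numpy's default, the classic "type 7" rule), the
IQR is Q3 - Q1 under that rule, and the MAD is the unscaled
``median(|x - median(x)|)`` (no normal-consistency factor — it is reported
descriptively, not as a robust SD).
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SUMMARY_FIELDS",
    "ANTHROPOMETRIC_PARAMETERS",
    "summarize_field",
    "pearson_correlation",
    "linear_regression",
    "correlation_battery",
]

SUMMARY_FIELDS = ("mean", "median", "iqr", "mad", "p90", "p95")

# population-table column per anthropometric parameter
ANTHROPOMETRIC_PARAMETERS = {
    "weight": "weight_kg",
    "height": "height_m",
    "bmi": "bmi",
    "tibia_length": "tibia_length_mm",
}

QUANTITIES = ("hydrostatic", "oct_shear", "max_principal", "j2")
REGIONS = ("gap", "callus")


def summarize_field(values, weights=None) -> dict[str, float]:
    """Six descriptive statistics of one invariant field.

    ``weights`` (e.g. cell areas) are optional; by default every cell counts
    equally, matching a per-mesh-cell evaluation.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty field")
    if weights is None:
        med = float(np.median(x))
        q1, q3, p90, p95 = np.percentile(x, [25, 75, 90, 95])
        return {
            "mean": float(np.mean(x)),
            "median": med,
            "iqr": float(q3 - q1),
            "mad": float(np.median(np.abs(x - med))),
            "p90": float(p90),
            "p95": float(p95),
        }
    w = np.asarray(weights, dtype=float)
    if w.shape != x.shape or np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be non-negative, same shape, not all zero")
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    cdf = (np.cumsum(ws) - 0.5 * ws) / ws.sum()

    def q(p):
        return float(np.interp(p, cdf, xs))

    med = q(0.5)
    # weighted MAD: weighted median of absolute deviations
    dev = np.abs(x - med)
    order_d = np.argsort(dev)
    cdf_d = (np.cumsum(w[order_d]) - 0.5 * w[order_d]) / w.sum()
    return {
        "mean": float(np.average(x, weights=w)),
        "median": med,
        "iqr": q(0.75) - q(0.25),
        "mad": float(np.interp(0.5, cdf_d, dev[order_d])),
        "p90": q(0.90),
        "p95": q(0.95),
    }


def pearson_correlation(x, y) -> tuple[float, float]:
    """Sample Pearson r with its two-sided p-value.

    p comes from ``t = r * sqrt((n-2)/(1-r^2))`` on n-2 degrees of freedom.
    Constant input has no defined correlation and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def linear_regression(x, y) -> tuple[float, float, float]:
    """Ordinary least squares fit y = slope*x + intercept; returns r^2 too."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("regression undefined for constant x")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def correlation_battery(
    summaries: pd.DataFrame,
    population: pd.DataFrame,
    statistic: str = "median",
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Pearson battery: anthropometric parameter vs avatar-level invariant statistic.

    ``summaries`` must hold one row per avatar x landmark x region x quantity
    with the six statistic columns (see :func:`summarize_field`); the
    avatar-level ``statistic`` (median by default) is correlated against each
    anthropometric parameter.  Returns one row per parameter x landmark x
    region x quantity with r, two-sided p, n and a significance flag at
    ``alpha``.
    """
    if statistic not in SUMMARY_FIELDS:
        raise ValueError(f"statistic must be one of {SUMMARY_FIELDS}")
    pop = population.set_index("id")
    landmarks = sorted(summaries["landmark"].unique())
    rows = []
    grouped = summaries.set_index(["landmark", "region", "quantity"]).sort_index()
    for param, lm, region, quantity in product(
        ANTHROPOMETRIC_PARAMETERS, landmarks, REGIONS, QUANTITIES
    ):
        sub = grouped.loc[(lm, region, quantity)]
        x = pop.loc[sub["avatar_id"].to_numpy(), ANTHROPOMETRIC_PARAMETERS[param]].to_numpy()
        y = sub[statistic].to_numpy()
        r, p = pearson_correlation(x, y)
        rows.append(
            {
                "parameter": param,
                "landmark": lm,
                "region": region,
                "quantity": quantity,
                "r": r,
                "p": p,
                "n": int(len(y)),
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows)
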