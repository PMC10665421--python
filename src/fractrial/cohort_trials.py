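"""Cohort-resampling algorithms for anthropometric trial-arm imbalance.

Two procedures quantify how often two randomized trial cohorts drawn from
the same population differ both *statistically* (pooled two-sample t-test,
two-sided, alpha = 0.05) and *clinically* (Cohen's d above a threshold):

* Algorithm A draws disjoint pairs of cohorts (default n = 30 each) from the
  300-avatar population until a pair differs significantly and relevantly on
  one chosen anthropometric parameter (default |d| >= 0.9); the pair can then
  be pushed back through the correlation battery per cohort.
* Algorithm B, on a large metadata-only population (default 10^6 subjects),
  counts how many pair draws are needed until the stopping rule fires, for
  trial sizes 10-60 per cohort and Cohen's d thresholds 0.5-0.9, averaging
  the count over 100 independent repeats.

For equal cohort sizes n the pivotal identity ``t = d * sqrt(n/2)`` links the
two stopping conditions, making the iteration count geometric with success
probability P(|t| >= max(t_alpha, d_min * sqrt(n/2))) when cohorts share one
distribution — the oracle used in the tests.

Both algorithms use Student's pooled-variance t-test, internally consistent
with the pooled-SD Cohen's d; Welch's variant is available behind a flag.
Within one Algorithm B sweep all d thresholds share the same draw sequence
(common random numbers), so the nested-event monotonicity of the mean
iteration count in the threshold holds exactly, not just in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import stdtr

from ._rng import stream

__all__ = [
    "MaxIterationsError",
    "CohortPairResult",
    "cohens_d",
    "two_sample_t",
    "stopping_rule",
    "algorithm_a",
    "algorithm_b",
]

DEFAULT_ALPHA = 0.05
DEFAULT_D_GRID = (0.5, 0.6, 0.7, 0.8, 0.9)
DEFAULT_TRIAL_SIZES = tuple(range(10, 61))


class MaxIterationsError(RuntimeError):
    """Raised when a stopping rule does not fire within the iteration cap."""

    def __init__(self, max_iter: int, message: str | None = None):
        self.max_iter = max_iter
        super().__init__(message or f"stopping rule not satisfied within {max_iter} iterations")


def _pooled_stats(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need at least 2 observations")
    v1 = a.var(ddof=1)
    v2 = b.var(ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise ValueError("zero pooled standard deviation: effect size undefined")
    return float(a.mean() - b.mean()), float(np.sqrt(sp2)), float(n1 + n2 - 2)


def cohens_d(sample1, sample2) -> float:
    """Standardized mean difference with pooled SD.

    ``d = (mean1 - mean2) / s_p`` where ``s_p^2`` pools the two sample
    variances with n-1 weights.  Conventionally |d| = 0.5 is a medium and
    |d| >= 0.8-0.9 a large effect.
    """
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    diff, sp, _ = _pooled_stats(a, b)
    return diff / sp


def two_sample_t(sample1, sample2, welch: bool = False) -> tuple[float, float]:
    """Two-sample t statistic and two-sided p-value.

    Default is Student's pooled-variance test, for which
    ``t = d * sqrt(n1*n2/(n1+n2))`` holds exactly with the pooled-SD Cohen's
    d.  ``welch=True`` switches to the unequal-variance form.
    """
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    if welch:
        from scipy import stats

        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    diff, sp, df = _pooled_stats(a, b)
    n1, n2 = a.size, b.size
    t = diff / (sp * np.sqrt(1.0 / n1 + 1.0 / n2))
    p = 2.0 * stdtr(df, -abs(t))
    return float(t), float(p)


def stopping_rule(sample1, sample2, d_min: float, alpha: float = DEFAULT_ALPHA) -> bool:
    """The significant-AND-relevant stopping condition both algorithms use.

    True iff the two-sided pooled t-test gives p < ``alpha`` and the pooled
    Cohen's d satisfies |d| >= ``d_min``.  A zero pooled SD cannot satisfy
    the rule and returns False.
    """
    try:
        _, p = two_sample_t(sample1, sample2)
        d = cohens_d(sample1, sample2)
    except ValueError:
        return False
    return p < alpha and abs(d) >= d_min


@dataclass(frozen=True)
class CohortPairResult:
    """A pair of disjoint cohorts satisfying the stopping rule."""

    parameter: str
    iteration_found: int
    cohort1: np.ndarray = field(repr=False)  # avatar ids
    cohort2: np.ndarray = field(repr=False)
    mean1: float = 0.0
    mean2: float = 0.0
    sd1: float = 0.0
    sd2: float = 0.0
    t: float = 0.0
    p: float = 1.0
    d: float = 0.0

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "iteration_found": self.iteration_found,
            "cohort1_ids": [int(i) for i in self.cohort1],
            "cohort2_ids": [int(i) for i in self.cohort2],
            "mean1": self.mean1,
            "mean2": self.mean2,
            "sd1": self.sd1,
            "sd2": self.sd2,
            "t": self.t,
            "p": self.p,
            "d": self.d,
        }


def _resolve_values(population, parameter: str) -> tuple[np.ndarray, np.ndarray]:
    """Parameter values and avatar ids from a population table or array."""
    if isinstance(population, pd.DataFrame):
        from .summary_stats import ANTHROPOMETRIC_PARAMETERS

        col = ANTHROPOMETRIC_PARAMETERS.get(parameter, parameter)
        values = population[col].to_numpy(dtype=float)
        ids = population["id"].to_numpy() if "id" in population else np.arange(len(values))
    else:
        values = np.asarray(population, dtype=float)
        ids = np.arange(values.size)
    return values, ids


def algorithm_a(
    population,
    n: int = 30,
    parameter: str = "bmi",
    d_min: float = 0.9,
    alpha: float = DEFAULT_ALPHA,
    max_iter: int = 100_000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> CohortPairResult:
    """Search for two disjoint cohorts differing significantly and relevantly.

    Repeatedly draws two disjoint simple-random cohorts of ``n`` without
    replacement and stops at the first iteration where the two-sided pooled
    t-test gives p < ``alpha`` AND |Cohen's d| >= ``d_min`` on ``parameter``.

    Raises :class:`MaxIterationsError` if the rule never fires within
    ``max_iter`` iterations (e.g. a constant parameter).
    """
    values, ids = _resolve_values(population, parameter)
    if values.size < 2 * n:
        raise ValueError("population must hold at least two cohorts")
    if rng is None:
        rng = stream(0 if seed is None else seed, "algorithm_a")
    for iteration in range(1, max_iter + 1):
        idx = rng.choice(values.size, size=2 * n, replace=False, shuffle=False)
        a, b = values[idx[:n]], values[idx[n:]]
        if stopping_rule(a, b, d_min, alpha):
            t, p = two_sample_t(a, b)
            d = cohens_d(a, b)
            return CohortPairResult(
                parameter=parameter,
                iteration_found=iteration,
                cohort1=ids[idx[:n]],
                cohort2=ids[idx[n:]],
                mean1=float(a.mean()),
                mean2=float(b.mean()),
                sd1=float(a.std(ddof=1)),
                sd2=float(b.std(ddof=1)),
                t=t,
                p=p,
                d=d,
            )
    raise MaxIterationsError(max_iter)


def algorithm_b(
    population,
    parameter: str = "bmi",
    trial_sizes=DEFAULT_TRIAL_SIZES,
    d_grid=DEFAULT_D_GRID,
    repeats: int = 100,
    alpha: float = DEFAULT_ALPHA,
    iter_cap: int = 1_000_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean number of cohort-pair draws until a significant + relevant pair.

    For every trial size (subjects *per cohort*), draws a fresh disjoint pair
    per iteration from the metadata population and counts iterations until
    p < ``alpha`` AND |d| >= threshold, simultaneously for every threshold in
    ``d_grid`` on a shared draw sequence.  The count is averaged over
    ``repeats`` independent runs.

    Runs that hit ``iter_cap`` are recorded as censored (the cap enters the
    mean as a lower bound) and flagged in the output.

    Returns a tidy DataFrame: trial_size, d_threshold, parameter,
    mean_iterations, sd_iterations, repeats, censored_runs.
    """
    values, _ = _resolve_values(population, parameter)
    d_grid = np.sort(np.asarray(d_grid, dtype=float))
    trial_sizes = [int(s) for s in trial_sizes]
    if values.size < 2 * max(trial_sizes):
        raise ValueError("population too small for the largest trial size")
    rows = []
    for size in trial_sizes:
        df = 2 * size - 2
        counts = np.empty((repeats, d_grid.size))
        censored = np.zeros((repeats, d_grid.size), dtype=bool)
        for rep in range(repeats):
            rng = stream(seed, "algorithm_b", size, rep)
            found = np.full(d_grid.size, -1, dtype=np.int64)
            it = 0
            while it < iter_cap and (found < 0).any():
                it += 1
                idx = rng.choice(values.size, size=2 * size, replace=False, shuffle=False)
                a, b = values[idx[:size]], values[idx[size:]]
                try:
                    diff, sp, _ = _pooled_stats(a, b)
                except ValueError:
                    continue
                d = diff / sp
                t = d * np.sqrt(size / 2.0)
                p = 2.0 * stdtr(df, -abs(t))
                if p < alpha:
                    hit = (found < 0) & (abs(d) >= d_grid)
                    found[hit] = it
            censored[rep] = found < 0
            found[found < 0] = iter_cap
            counts[rep] = found
        for k, thr in enumerate(d_grid):
            rows.append(
                {
                    "trial_size": size,
                    "d_threshold": float(thr),
                    "parameter": parameter,
                    "mean_iterations": float(counts[:, k].mean()),
                    "sd_iterations": float(counts[:, k].std(ddof=1)) if repeats > 1 else float("nan"),
                    "repeats": repeats,
                    "censored_runs": int(censored[:, k].sum()),
                }
            )
    return pd.DataFrame(rows)
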