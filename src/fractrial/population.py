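"""Synthesis of the in silico avatar population.

Avatars are male subjects aged 20-60 with body height restricted to
1.60-1.95 m and BMI to 18-35 (underweight, adiposity, and pediatric or
geriatric bone physiology are excluded by design).  The cohort is split into
five-year age groups; within each group, height and BMI are drawn
independently from truncated normal distributions, body weight follows as
``BMI * height^2`` and tibia length from a forensic-medicine style linear
model on stature plus a residual noise term.

The per-group distribution moments shipped as defaults are plausible
stand-ins for German male census statistics and are fully configurable;
they are *not* measured values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

__all__ = [
    "PopulationConfig",
    "Avatar",
    "sample_truncated",
    "derive_weight",
    "compute_bmi",
    "derive_tibia_length",
    "generate_population",
    "summarize_population",
    "avatars_from_frame",
]


class PopulationConfig(BaseModel):
    """Age-stratified truncated-normal population model.

    Per-group parameters may be given as a scalar (applied to every group) or
    as one value per age group.
    """

    model_config = ConfigDict(extra="forbid")

    age_min: float = 20.0
    age_max: float = 60.0
    age_group_width: float = 5.0
    group_weights: list[float] | None = None
    height_mean: float | list[float] = 1.78  # m
    height_sd: float | list[float] = 0.07  # m
    bmi_mean: float | list[float] | None = None  # kg/m^2; default ramps 25.0 -> 27.5
    bmi_sd: float | list[float] = 3.5  # kg/m^2
    height_bounds: tuple[float, float] = (1.60, 1.95)  # m
    bmi_bounds: tuple[float, float] = (18.0, 35.0)  # kg/m^2
    tibia_intercept: float = 81.9  # cm
    tibia_slope: float = 2.42
    tibia_resid_sd: float | list[float] = 1.2  # cm
    seed: int = 0

    @property
    def n_groups(self) -> int:
        span = self.age_max - self.age_min
        return int(round(span / self.age_group_width))

    @model_validator(mode="after")
    def _check(self) -> "PopulationConfig":
        if self.age_max <= self.age_min:
            raise ValueError("age_max must exceed age_min")
        span = self.age_max - self.age_min
        n = span / self.age_group_width
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ValueError("age range must be an integer number of group widths")
        for name in ("height_bounds", "bmi_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be ordered (lo < hi), got {(lo, hi)}")
        if self.group_weights is not None:
            w = np.asarray(self.group_weights, dtype=float)
            if len(w) != self.n_groups:
                raise ValueError(
                    f"group_weights needs {self.n_groups} entries, got {len(w)}"
                )
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("group_weights must be non-negative and sum to 1")
        for name in ("height_sd", "bmi_sd", "tibia_resid_sd"):
            if np.any(np.asarray(self._per_group(name)) < 0):
                raise ValueError(f"{name} must be >= 0")
        if self.tibia_slope <= 0:
            raise ValueError("tibia_slope must be positive")
        return self

    def _per_group(self, name: str) -> np.ndarray:
        value = getattr(self, name)
        if name == "bmi_mean" and value is None:
            return np.linspace(25.0, 27.5, self.n_groups)
        arr = np.atleast_1d(np.asarray(value, dtype=float))
        if arr.size == 1:
            return np.full(self.n_groups, arr[0])
        if arr.size != self.n_groups:
            raise ValueError(f"{name} needs 1 or {self.n_groups} values")
        return arr

    def weights(self) -> np.ndarray:
        if self.group_weights is None:
            return np.full(self.n_groups, 1.0 / self.n_groups)
        return np.asarray(self.group_weights, dtype=float)


@dataclass(frozen=True)
class Avatar:
    """One synthetic trial subject, defined entirely by anthropometric metadata."""

    id: int
    age_group: int
    height: float  # m
    bmi: float  # kg/m^2
    weight: float  # kg
    tibia_length: float  # mm


def sample_truncated(
    mean: float,
    sd: float,
    lo: float,
    hi: float,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Draw from a normal(mean, sd) law restricted to [lo, hi].

    A degenerate ``sd == 0`` returns the mean (which must lie inside the
    interval).  Raises ``ValueError`` when the interval carries numerically
    zero probability mass.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if not lo < hi:
        raise ValueError("truncation interval must satisfy lo < hi")
    if sd == 0:
        if not lo <= mean <= hi:
            raise ValueError("degenerate distribution (sd=0) lies outside [lo, hi]")
        return float(mean) if size is None else np.full(size, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    mass = stats.norm.cdf(b) - stats.norm.cdf(a)
    if mass < 1e-12:
        raise ValueError(
            f"truncation interval [{lo}, {hi}] carries ~zero mass for "
            f"N({mean}, {sd}^2)"
        )
    draws = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)
    return float(draws) if size is None else draws


def derive_weight(bmi, height):
    """Body weight in kg from BMI (kg/m^2) and height (m): ``bmi * height^2``."""
    bmi = np.asarray(bmi, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(bmi <= 0) or np.any(height <= 0):
        raise ValueError("bmi and height must be positive")
    out = bmi * height**2
    return float(out) if out.ndim == 0 else out


def compute_bmi(weight, height):
    """BMI in kg/m^2 from weight (kg) and height (m); inverse of derive_weight."""
    weight = np.asarray(weight, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(weight <= 0) or np.any(height <= 0):
        raise ValueError("weight and height must be positive")
    out = weight / height**2
    return float(out) if out.ndim == 0 else out


def derive_tibia_length(
    height,
    age_group,
    config: PopulationConfig,
    rng: np.random.Generator | None = None,
):
    """Tibia length in mm from stature via the inverse stature formula.

    ``length_cm = (height_cm - intercept) / slope + N(0, resid_sd)``, with the
    residual SD taken per age group.  With zero residual SD the mapping is a
    deterministic function of height (1.79 m -> ~401 mm).
    """
    height = np.asarray(height, dtype=float)
    lo, hi = config.height_bounds
    if np.any(height < lo) or np.any(height > hi):
        raise ValueError("height outside configured bounds")
    resid_sd = config._per_group("tibia_resid_sd")[np.asarray(age_group, dtype=int)]
    length_cm = (height * 100.0 - config.tibia_intercept) / config.tibia_slope
    if np.any(resid_sd > 0):
        if rng is None:
            raise ValueError("rng required when tibia_resid_sd > 0")
        length_cm = length_cm + rng.normal(0.0, resid_sd)
    out = length_cm * 10.0
    return float(out) if out.ndim == 0 else out


def generate_population(
    config: PopulationConfig,
    n: int,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate ``n`` avatars as a DataFrame.

    Columns: ``id, age_group, height_m, bmi, weight_kg, tibia_length_mm``.
    Age group is sampled from the configured weights; height and BMI are drawn
    independently per group from their truncated normals.  Fully reproducible:
    the same config (seed) yields the identical table.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        from ._rng import stream

        rng = stream(config.seed, "population")
    groups = rng.choice(config.n_groups, size=n, p=config.weights())
    h_mean, h_sd = config._per_group("height_mean"), config._per_group("height_sd")
    b_mean, b_sd = config._per_group("bmi_mean"), config._per_group("bmi_sd")
    height = np.empty(n)
    bmi = np.empty(n)
    for g in range(config.n_groups):
        mask = groups == g
        m = int(mask.sum())
        if m == 0:
            continue
        height[mask] = sample_truncated(
            h_mean[g], h_sd[g], *config.height_bounds, rng, size=m
        )
        bmi[mask] = sample_truncated(
            b_mean[g], b_sd[g], *config.bmi_bounds, rng, size=m
        )
    weight = derive_weight(bmi, height)
    tibia = derive_tibia_length(height, groups, config, rng)
    return pd.DataFrame(
        {
            "id": np.arange(n, dtype=int),
            "age_group": groups.astype(int),
            "height_m": height,
            "bmi": bmi,
            "weight_kg": weight,
            "tibia_length_mm": tibia,
        }
    )


def avatars_from_frame(frame: pd.DataFrame) -> list[Avatar]:
    """Materialize Avatar records from a population table."""
    return [
        Avatar(
            id=int(r.id),
            age_group=int(r.age_group),
            height=float(r.height_m),
            bmi=float(r.bmi),
            weight=float(r.weight_kg),
            tibia_length=float(r.tibia_length_mm),
        )
        for r in frame.itertuples(index=False)
    ]


def summarize_population(avatars: pd.DataFrame | Sequence[Avatar]) -> pd.DataFrame:
    """Per-age-group mean and SD of height, BMI and weight.

    Groups with a single avatar report an SD of NaN (sample SD undefined).
    """
    if not isinstance(avatars, pd.DataFrame):
        avatars = pd.DataFrame(
            {
                "age_group": [a.age_group for a in avatars],
                "height_m": [a.height for a in avatars],
                "bmi": [a.bmi for a in avatars],
                "weight_kg": [a.weight for a in avatars],
            }
        )
    if len(avatars) == 0:
        raise ValueError("empty population")
    agg = avatars.groupby("age_group")[["height_m", "bmi", "weight_kg"]].agg(
        ["mean", "std", "count"]
    )
    agg.columns = ["_".join(c) for c in agg.columns]
    return agg.reset_index()
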