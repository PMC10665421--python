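"""Stance-phase load landmarks and body-weight rescaling.

Internal loads at the fracture level are described at five stance-phase
landmarks S1-S5 (six components each: three forces, three moments),
referenced to a 755 N body weight.  Per avatar, every component is rescaled
by ``lambda = weight * g / reference_bodyweight`` so the load *shape* over
the stance phase is shared while its magnitude tracks body weight.

Coordinate convention: right-handed, x anterior, y medial, z superior.
Compressive axial force at the fracture cross-section has Fz < 0.

The default landmark table is an invented, configurable stand-in expressed
in percent body weight (forces) and percent body weight times metre
(moments): S1-S3 are sub-maximal early/mid-stance loads, S4 carries the
axial force peak (~2.6x body weight) and S5 the bending-moment peak with a
reduced axial force.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = ["LANDMARKS", "LandmarkLoadSet", "GaitLoadConfig", "load_landmark_table", "scale_loads"]

LANDMARKS = ("S1", "S2", "S3", "S4", "S5")
STANDARD_GRAVITY = 9.81  # m/s^2

# Rows: landmark -> (Fx, Fy, Fz) in %BW and (Mx, My, Mz) in %BW*m.
_DEFAULT_TABLE_PCT_BW = {
    "S1": (10.0, 6.0, -190.0, 0.40, 0.50, 0.15),
    "S2": (6.0, 4.0, -230.0, 0.50, 0.70, 0.20),
    "S3": (5.0, 4.0, -210.0, 0.60, 0.80, 0.25),
    "S4": (8.0, 5.0, -260.0, 0.70, 0.90, 0.30),
    "S5": (4.0, 3.0, -120.0, 1.20, 1.60, 0.50),
}


class GaitLoadConfig(BaseModel):
    """Landmark table in percent-body-weight units plus the reference weight."""

    model_config = ConfigDict(extra="forbid")

    reference_bodyweight: float = 755.0  # N
    table_pct_bw: dict[str, tuple[float, float, float, float, float, float]] = (
        _DEFAULT_TABLE_PCT_BW
    )

    @model_validator(mode="after")
    def _check(self) -> "GaitLoadConfig":
        if self.reference_bodyweight <= 0:
            raise ValueError("reference_bodyweight must be positive")
        if tuple(self.table_pct_bw) != LANDMARKS:
            raise ValueError(
                f"landmark table must have exactly the rows {LANDMARKS}, "
                f"got {tuple(self.table_pct_bw)}"
            )
        for lm, row in self.table_pct_bw.items():
            if not np.all(np.isfinite(row)):
                raise ValueError(f"non-finite load components at {lm}")
        return self


class LandmarkLoadSet:
    """Six-component internal loads at S1-S5, tied to a reference body weight.

    Forces in N, moments in N*m.
    """

    def __init__(self, forces: np.ndarray, moments: np.ndarray, reference_bodyweight: float = 755.0):
        forces = np.asarray(forces, dtype=float)
        moments = np.asarray(moments, dtype=float)
        if forces.shape != (5, 3) or moments.shape != (5, 3):
            raise ValueError("forces and moments must each be (5, 3) arrays")
        if not (np.all(np.isfinite(forces)) and np.all(np.isfinite(moments))):
            raise ValueError("non-finite load components")
        if reference_bodyweight <= 0:
            raise ValueError("reference_bodyweight must be positive")
        self.forces = forces
        self.moments = moments
        self.reference_bodyweight = float(reference_bodyweight)

    def __getitem__(self, landmark: str) -> tuple[np.ndarray, np.ndarray]:
        i = LANDMARKS.index(landmark)
        return self.forces[i], self.moments[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.hstack([self.forces, self.moments]),
            index=pd.Index(LANDMARKS, name="landmark"),
            columns=["Fx_N", "Fy_N", "Fz_N", "Mx_Nm", "My_Nm", "Mz_Nm"],
        ).reset_index()

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return (
            isinstance(other, LandmarkLoadSet)
            and np.array_equal(self.forces, other.forces)
            and np.array_equal(self.moments, other.moments)
            and self.reference_bodyweight == other.reference_bodyweight
        )


def load_landmark_table(config: GaitLoadConfig | None = None) -> LandmarkLoadSet:
    """Resolve the percent-body-weight landmark table to absolute N / N*m."""
    config = config or GaitLoadConfig()
    bw = config.reference_bodyweight
    rows = np.array([config.table_pct_bw[lm] for lm in LANDMARKS], dtype=float)
    forces = rows[:, :3] / 100.0 * bw
    moments = rows[:, 3:] / 100.0 * bw
    return LandmarkLoadSet(forces, moments, reference_bodyweight=bw)


def scale_loads(loads: LandmarkLoadSet, avatar, g: float = STANDARD_GRAVITY) -> LandmarkLoadSet:
    """Rescale the landmark loads to an avatar's body weight.

    Every force and moment component is multiplied by
    ``lambda = weight_kg * g / reference_bodyweight``; directions are
    preserved and scaling is homogeneous (linear in weight).
    """
    weight = float(getattr(avatar, "weight", avatar))
    if weight <= 0:
        raise ValueError("avatar weight must be positive")
    lam = weight * g / loads.reference_bodyweight
    return LandmarkLoadSet(
        loads.forces * lam,
        loads.moments * lam,
        reference_bodyweight=loads.reference_bodyweight,
    )
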