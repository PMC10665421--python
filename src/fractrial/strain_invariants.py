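"""Strain-tensor invariants driving the mechanobiology of fracture healing.

Four scalar quantities are evaluated per mesh cell from the symmetric strain
tensor (tensor shear convention, ``eps_xy = gamma_xy / 2``):

* hydrostatic strain — the mean normal strain ``tr(eps) / 3``, the volume
  change part (compression is negative).  The volumetric strain ``tr(eps)``
  is the trivially related alternative and is exposed too; switching between
  them only rescales by 3 and leaves Pearson correlations unchanged.
* octahedral shear strain — the shape-distortion invariant
  ``(2/3) * sqrt((e1-e2)^2 + (e2-e3)^2 + (e3-e1)^2)``.
* maximum principal strain — the largest eigenvalue.
* J2 — the second invariant of the deviatoric strain tensor,
  ``(1/2) * sum(dev_ij^2)``.

All functions accept a single ``(3, 3)`` tensor or a stacked ``(n, 3, 3)``
array and are rotation invariant.

An optional mechanoregulation classifier maps each cell's (hydrostatic,
octahedral shear) pair onto a tissue-outcome label over a rectangular grid
of thresholds.  No canonical threshold values ship enabled by default: the
boundaries in the literature vary, so the grid is entirely user-configured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "principal_strains",
    "hydrostatic_strain",
    "volumetric_strain",
    "deviatoric",
    "j2",
    "octahedral_shear",
    "max_principal_strain",
    "invariant_table",
    "MechanoregulationGrid",
    "classify_mechanoregulation",
]

_SYM_ATOL = 1e-9


def _as_sym(tensor) -> np.ndarray:
    t = np.asarray(tensor, dtype=float)
    if t.shape[-2:] != (3, 3):
        raise ValueError("expected (..., 3, 3) strain tensor(s)")
    if not np.allclose(t, np.swapaxes(t, -1, -2), atol=_SYM_ATOL, rtol=0):
        raise ValueError("strain tensor must be symmetric")
    return t


def principal_strains(tensor) -> np.ndarray:
    """Eigenvalues of the symmetric strain tensor, sorted descending."""
    t = _as_sym(tensor)
    vals = np.linalg.eigvalsh(t)
    return vals[..., ::-1]


def hydrostatic_strain(tensor):
    """Mean normal strain tr(eps)/3."""
    t = _as_sym(tensor)
    out = np.trace(t, axis1=-2, axis2=-1) / 3.0
    return float(out) if np.ndim(out) == 0 else out


def volumetric_strain(tensor):
    """Volume change tr(eps) = 3 * hydrostatic strain."""
    t = _as_sym(tensor)
    out = np.trace(t, axis1=-2, axis2=-1)
    return float(out) if np.ndim(out) == 0 else out


def deviatoric(tensor) -> np.ndarray:
    """Traceless deviatoric part eps - (tr eps / 3) I."""
    t = _as_sym(tensor)
    mean = np.trace(t, axis1=-2, axis2=-1)[..., None, None] / 3.0
    return t - mean * np.eye(3)


def j2(tensor):
    """Second invariant of the deviatoric strain, (1/2) sum(dev_ij^2) >= 0."""
    d = deviatoric(tensor)
    out = 0.5 * np.sum(d * d, axis=(-2, -1))
    return float(out) if np.ndim(out) == 0 else out


def octahedral_shear(tensor):
    """Octahedral shear strain (2/3) sqrt(sum of squared principal gaps).

    Identically equal to ``2 * sqrt(2 * J2 / 3)``.
    """
    e = principal_strains(tensor)
    e1, e2, e3 = e[..., 0], e[..., 1], e[..., 2]
    out = (2.0 / 3.0) * np.sqrt((e1 - e2) ** 2 + (e2 - e3) ** 2 + (e3 - e1) ** 2)
    return float(out) if np.ndim(out) == 0 else out


def max_principal_strain(tensor):
    """Largest eigenvalue of the strain tensor."""
    out = principal_strains(tensor)[..., 0]
    return float(out) if np.ndim(out) == 0 else out


def invariant_table(tensors: np.ndarray) -> dict[str, np.ndarray]:
    """All four invariants of a stacked (n, 3, 3) tensor array."""
    return {
        "hydrostatic": np.atleast_1d(hydrostatic_strain(tensors)),
        "oct_shear": np.atleast_1d(octahedral_shear(tensors)),
        "max_principal": np.atleast_1d(max_principal_strain(tensors)),
        "j2": np.atleast_1d(j2(tensors)),
    }


@dataclass(frozen=True)
class MechanoregulationGrid:
    """Rectangular partition of the (hydrostatic, octahedral shear) plane.

    ``hydro_edges`` (sorted, interior breakpoints) split the hydrostatic axis
    into ``len+1`` bands; ``shear_edges`` likewise for the shear axis.
    ``labels[i][j]`` names the outcome for hydrostatic band ``i`` and shear
    band ``j``.  Bands are closed below: a point exactly on an edge belongs
    to the band above the edge, i.e. the edge value starts a new band, so
    the lower region keeps points strictly below the boundary.
    """

    hydro_edges: tuple[float, ...]
    shear_edges: tuple[float, ...]
    labels: tuple[tuple[str, ...], ...] = field(default=())

    def __post_init__(self):
        he = np.asarray(self.hydro_edges, dtype=float)
        se = np.asarray(self.shear_edges, dtype=float)
        if np.any(np.diff(he) <= 0) or np.any(np.diff(se) <= 0):
            raise ValueError("threshold edges must be strictly increasing")
        lab = self.labels
        if len(lab) != he.size + 1 or any(len(row) != se.size + 1 for row in lab):
            raise ValueError(
                "labels must be a (n_hydro_bands x n_shear_bands) grid covering the plane"
            )


# Example grid (disabled by default in the pipeline): compression combined
# with low distortion favours bone, high distortion fibrous tissue.
EXAMPLE_GRID = MechanoregulationGrid(
    hydro_edges=(-0.0005, 0.0005),
    shear_edges=(0.0025, 0.05),
    labels=(
        ("bone", "cartilage", "fibrous"),
        ("bone", "bone", "fibrous"),
        ("bone", "fibrous", "fibrous"),
    ),
)


def classify_mechanoregulation(hydrostatic, oct_shear, grid: MechanoregulationGrid) -> np.ndarray:
    """Tissue-outcome label per cell from its invariant pair.

    Deterministic: every point lands in exactly one rectangle of the grid
    (closed-below tie rule at boundaries).
    """
    h = np.atleast_1d(np.asarray(hydrostatic, dtype=float))
    s = np.atleast_1d(np.asarray(oct_shear, dtype=float))
    i = np.searchsorted(np.asarray(grid.hydro_edges), h, side="right")
    j = np.searchsorted(np.asarray(grid.shear_edges), s, side="right")
    labels = np.asarray(grid.labels, dtype=object)
    return labels[i, j]
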