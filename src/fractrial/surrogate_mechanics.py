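"""Surrogate mechanics of a nailed tibia fracture gap.

This module is a deliberately simple, fully documented stand-in for a
patient-specific finite-element model: an idealized circular tibia
cross-section stabilized by an intramedullary nail, with a compliant
tissue layer of height ``h`` (the fracture gap) bridged in parallel by the
nail and the soft tissue filling gap and callus.

The mechanical chain is linear throughout:

1. Section properties of nail and tissue annulus (areas, second moments).
2. Parallel-spring stiffnesses across the gap (axial, bending, shear,
   torsion), Euler-Bernoulli style: ``k_ax = (E_n A_n + E_t A_t) / h`` etc.
3. Interfragmentary movement: the six relative motion components of the
   fragments under one landmark load, ``delta_z = Fz / k_ax`` and so on.
4. A per-cell strain tensor field over a polar mesh of the gap and callus
   annuli, reconstructed from the rigid-fragment kinematics:
   ``eps_zz = (dz + phix*y - phiy*x) / h``, engineering shears
   ``gamma_xz = (dx - thz*y) / h`` and ``gamma_yz = (dy + thz*x) / h``, and
   an unconfined Poisson response ``eps_xx = eps_yy = -nu_t * eps_zz``.

Strain tensors store *tensor* shear components (eps_xy = gamma_xy / 2).

Units: lengths mm, forces N, moments N*m (converted to N*mm internally),
moduli MPa (= N/mm^2), so strains are dimensionless.

Because every step is linear, the whole field scales exactly with the load
scale factor, hence with body weight at fixed geometry — the property the
downstream correlation analysis depends on.  The tibia section radius
scales with tibia length, which ties the gap mechanics to stature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "SurrogateGeometry",
    "Materials",
    "Mesh",
    "density_to_modulus",
    "section_properties",
    "gap_kinematics",
    "build_mesh",
    "cell_strain_field",
    "strain_tensors",
]

# Density-modulus power law for tibial bone, E in MPa for rho_app in g/cm^3.
DENSITY_MODULUS_COEFF = 6570.0
DENSITY_MODULUS_EXP = 1.37


class SurrogateGeometry(BaseModel):
    """Idealized circular cross-section of the fractured, nailed tibia.

    The outer radius scales linearly with tibia length (``radius_factor``),
    the callus annulus extends beyond the cortex, and the fracture gap is a
    tissue layer of height ``gap_height`` between the fragments.
    """

    model_config = ConfigDict(extra="forbid")

    tibia_length: float = 397.0  # mm
    radius_factor: float = 0.028  # outer radius = factor * tibia length
    cortical_fraction: float = 0.35  # cortical thickness / outer radius
    nail_radius: float = 5.5  # mm (11 mm nail)
    gap_height: float = 3.0  # mm
    callus_factor: float = 1.3  # callus outer radius / outer radius
    n_r_gap: int = 10
    n_theta_gap: int = 48
    n_r_callus: int = 6
    n_theta_callus: int = 48

    @property
    def outer_radius(self) -> float:
        return self.radius_factor * self.tibia_length

    @property
    def inner_cortical_radius(self) -> float:
        return self.outer_radius * (1.0 - self.cortical_fraction)

    @property
    def callus_outer_radius(self) -> float:
        return self.callus_factor * self.outer_radius

    @model_validator(mode="after")
    def _check(self) -> "SurrogateGeometry":
        vals = [
            self.tibia_length,
            self.radius_factor,
            self.cortical_fraction,
            self.nail_radius,
            self.gap_height,
            self.n_r_gap,
            self.n_theta_gap,
            self.n_r_callus,
            self.n_theta_callus,
        ]
        if any(v <= 0 for v in vals):
            raise ValueError("all geometry parameters must be positive")
        if self.callus_factor <= 1.0:
            raise ValueError("callus_factor must exceed 1")
        if not self.nail_radius < self.inner_cortical_radius:
            raise ValueError("nail must fit inside the medullary canal")
        return self


class Materials(BaseModel):
    """Linear-elastic constants of the load-sharing constituents."""

    model_config = ConfigDict(extra="forbid")

    nail_E: float = 110_000.0  # MPa (titanium alloy)
    nail_nu: float = 0.3
    tissue_E: float = 3.0  # MPa (initial connective tissue)
    tissue_nu: float = 0.3
    density_modulus_coeff: float = DENSITY_MODULUS_COEFF
    density_modulus_exp: float = DENSITY_MODULUS_EXP
    shear_correction: float = 0.9
    # Elastic-fragment mode: when a fragment apparent density is given, the
    # cortical fragments act as series springs with E from the density law;
    # by default (None) the fragments are rigid and only the gap deforms.
    fragment_density: float | None = None  # g/cm^3
    fragment_length: float = 20.0  # mm per fragment

    @model_validator(mode="after")
    def _check(self) -> "Materials":
        if self.nail_E <= 0 or self.tissue_E <= 0:
            raise ValueError("elastic moduli must be positive")
        for nu in (self.nail_nu, self.tissue_nu):
            if not 0 <= nu < 0.5:
                raise ValueError("Poisson ratio must lie in [0, 0.5)")
        return self

    @property
    def nail_G(self) -> float:
        return self.nail_E / (2.0 * (1.0 + self.nail_nu))

    @property
    def tissue_G(self) -> float:
        return self.tissue_E / (2.0 * (1.0 + self.tissue_nu))


def density_to_modulus(rho_app, coeff: float = DENSITY_MODULUS_COEFF, exp: float = DENSITY_MODULUS_EXP):
    """Young's modulus in MPa from apparent density in g/cm^3.

    Power law ``E = 6570 * rho_app^1.37`` calibrated for tibial bone.
    """
    rho = np.asarray(rho_app, dtype=float)
    if np.any(rho < 0):
        raise ValueError("apparent density must be >= 0")
    out = coeff * rho**exp
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class StiffnessBundle:
    """Section properties and combined parallel-spring stiffnesses.

    Areas in mm^2, second moments in mm^4; stiffnesses in N/mm (translation)
    and N*mm/rad (rotation).
    """

    nail_area: float
    tissue_area: float
    nail_I: float
    tissue_I: float
    nail_J: float
    tissue_J: float
    k_axial: float
    k_bend_x: float
    k_bend_y: float
    k_shear: float
    k_torsion: float


def section_properties(geom: SurrogateGeometry, mat: Materials) -> StiffnessBundle:
    """Parallel nail + tissue-annulus stiffnesses across the gap.

    The nail is a solid circle of radius ``nail_radius``; the tissue annulus
    spans from the nail surface to the callus outer radius (gap and callus
    tissue both bridge the fracture).  The section is axisymmetric, so
    I_x = I_y.
    """
    r_n = geom.nail_radius
    r_o = geom.callus_outer_radius
    h = geom.gap_height
    A_n = np.pi * r_n**2
    I_n = np.pi * r_n**4 / 4.0
    J_n = 2.0 * I_n
    A_t = np.pi * (r_o**2 - r_n**2)
    I_t = np.pi * (r_o**4 - r_n**4) / 4.0
    J_t = 2.0 * I_t
    k_ax = (mat.nail_E * A_n + mat.tissue_E * A_t) / h
    k_bend = (mat.nail_E * I_n + mat.tissue_E * I_t) / h
    k_sh = mat.shear_correction * (mat.nail_G * A_n + mat.tissue_G * A_t) / h
    k_tor = (mat.nail_G * J_n + mat.tissue_G * J_t) / h
    if mat.fragment_density is not None:
        # Series combination with the two cortical fragments, whose modulus
        # comes from the density-modulus power law.
        E_b = density_to_modulus(
            mat.fragment_density, mat.density_modulus_coeff, mat.density_modulus_exp
        )
        G_b = E_b / (2.0 * (1.0 + mat.tissue_nu))
        r_c_out, r_c_in = geom.outer_radius, geom.inner_cortical_radius
        A_c = np.pi * (r_c_out**2 - r_c_in**2)
        I_c = np.pi * (r_c_out**4 - r_c_in**4) / 4.0
        L = 2.0 * mat.fragment_length  # both fragments in series
        k_ax = 1.0 / (1.0 / k_ax + L / (E_b * A_c))
        k_bend = 1.0 / (1.0 / k_bend + L / (E_b * I_c))
        k_sh = 1.0 / (1.0 / k_sh + L / (mat.shear_correction * G_b * A_c))
        k_tor = 1.0 / (1.0 / k_tor + L / (G_b * 2.0 * I_c))
    return StiffnessBundle(
        nail_area=A_n,
        tissue_area=A_t,
        nail_I=I_n,
        tissue_I=I_t,
        nail_J=J_n,
        tissue_J=J_t,
        k_axial=k_ax,
        k_bend_x=k_bend,
        k_bend_y=k_bend,
        k_shear=k_sh,
        k_torsion=k_tor,
    )


@dataclass(frozen=True)
class GapMotion:
    """Interfragmentary movement: translations in mm, rotations in rad."""

    dx: float
    dy: float
    dz: float
    phi_x: float
    phi_y: float
    theta_z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.dz, self.phi_x, self.phi_y, self.theta_z])


def gap_kinematics(force_N: np.ndarray, moment_Nm: np.ndarray, stiff: StiffnessBundle) -> GapMotion:
    """Relative fragment motion under one landmark load (linear springs).

    ``dz = Fz / k_axial``, ``phi_x = Mx / k_bend_x`` and so on; moments are
    converted from N*m to N*mm to match the mm-MPa unit system.
    """
    for k in (stiff.k_axial, stiff.k_bend_x, stiff.k_bend_y, stiff.k_shear, stiff.k_torsion):
        if k <= 0:
            raise ValueError("all stiffnesses must be positive")
    Fx, Fy, Fz = np.asarray(force_N, dtype=float)
    Mx, My, Mz = np.asarray(moment_Nm, dtype=float) * 1000.0  # N*m -> N*mm
    return GapMotion(
        dx=Fx / stiff.k_shear,
        dy=Fy / stiff.k_shear,
        dz=Fz / stiff.k_axial,
        phi_x=Mx / stiff.k_bend_x,
        phi_y=My / stiff.k_bend_y,
        theta_z=Mz / stiff.k_torsion,
    )


@dataclass(frozen=True)
class Mesh:
    """Polar cell mesh over the gap and callus annuli (cell centroids)."""

    x: np.ndarray  # mm
    y: np.ndarray  # mm
    area: np.ndarray  # mm^2
    region: np.ndarray  # 'gap' | 'callus'
    cell_id: np.ndarray

    def __len__(self) -> int:
        return self.x.size


def _polar_annulus(r_in: float, r_out: float, n_r: int, n_theta: int):
    """Centroids and exact areas of an annulus split into polar cells."""
    r_edges = np.linspace(r_in, r_out, n_r + 1)
    t_edges = np.linspace(0.0, 2.0 * np.pi, n_theta + 1)
    r_lo, r_hi = r_edges[:-1], r_edges[1:]
    t_lo, t_hi = t_edges[:-1], t_edges[1:]
    # area centroid radius of a polar sector cell
    r_c = (2.0 / 3.0) * (r_hi**3 - r_lo**3) / (r_hi**2 - r_lo**2)
    t_c = 0.5 * (t_lo + t_hi)
    R, T = np.meshgrid(r_c, t_c, indexing="ij")
    area = np.outer(0.5 * (r_hi**2 - r_lo**2), t_hi - t_lo)
    return (R * np.cos(T)).ravel(), (R * np.sin(T)).ravel(), area.ravel()


def build_mesh(geom: SurrogateGeometry) -> Mesh:
    """Discretize the gap annulus (nail to cortex) and callus annulus."""
    gx, gy, ga = _polar_annulus(
        geom.nail_radius, geom.outer_radius, geom.n_r_gap, geom.n_theta_gap
    )
    cx, cy, ca = _polar_annulus(
        geom.outer_radius, geom.callus_outer_radius, geom.n_r_callus, geom.n_theta_callus
    )
    x = np.concatenate([gx, cx])
    y = np.concatenate([gy, cy])
    area = np.concatenate([ga, ca])
    region = np.concatenate(
        [np.full(gx.size, "gap"), np.full(cx.size, "callus")]
    )
    return Mesh(x=x, y=y, area=area, region=region, cell_id=np.arange(x.size))


def cell_strain_field(
    motion: GapMotion,
    geom: SurrogateGeometry,
    mat: Materials,
    mesh: Mesh | None = None,
) -> pd.DataFrame:
    """Per-cell symmetric strain tensors from the interfragmentary movement.

    Returns a DataFrame with one row per mesh cell: position, area, region
    and the six tensor components (``exy = gamma_xy / 2`` convention).
    """
    if mesh is None:
        mesh = build_mesh(geom)
    h = geom.gap_height
    x, y = mesh.x, mesh.y
    ezz = (motion.dz + motion.phi_x * y - motion.phi_y * x) / h
    gxz = (motion.dx - motion.theta_z * y) / h
    gyz = (motion.dy + motion.theta_z * x) / h
    exx = -mat.tissue_nu * ezz
    return pd.DataFrame(
        {
            "cell_id": mesh.cell_id,
            "region": mesh.region,
            "x_mm": x,
            "y_mm": y,
            "area_mm2": mesh.area,
            "exx": exx,
            "eyy": exx.copy(),
            "ezz": ezz,
            "exy": np.zeros_like(ezz),
            "exz": 0.5 * gxz,
            "eyz": 0.5 * gyz,
        }
    )


def strain_tensors(field: pd.DataFrame) -> np.ndarray:
    """Stack the six tensor columns of a strain field into (n, 3, 3) arrays."""
    exx = field["exx"].to_numpy()
    eyy = field["eyy"].to_numpy()
    ezz = field["ezz"].to_numpy()
    exy = field["exy"].to_numpy()
    exz = field["exz"].to_numpy()
    eyz = field["eyz"].to_numpy()
    t = np.empty((len(field), 3, 3))
    t[:, 0, 0] = exx
    t[:, 1, 1] = eyy
    t[:, 2, 2] = ezz
    t[:, 0, 1] = t[:, 1, 0] = exy
    t[:, 0, 2] = t[:, 2, 0] = exz
    t[:, 1, 2] = t[:, 2, 1] = eyz
    return t
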