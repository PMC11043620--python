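"""Surface-occupancy normalization of protectant:target ratios.

Occupancy is the fraction of the (spherical) target surface theoretically
covered by protectant molecules, computed from concentrations, molecular
masses and hydrodynamic radii. The protectant contact area is the disc
pi * R_S^2; the target area is the sphere 4 * pi * R_S^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LiposomeGeometry", "ProteinTarget", "LiposomeTarget",
           "Protectant", "lipids_per_vesicle", "surface_occupancy",
           "ICMM_LIPID_FRACTIONS", "DEFAULT_HEADGROUP_AREAS", "LDH_RS_NM"]

# Inner-chloroplast-membrane-mimicking composition (fractions sum to 1).
ICMM_LIPID_FRACTIONS = {"MGDG": 0.40, "DGDG": 0.30, "SQDG": 0.15, "EPG": 0.15}

# Head-group areas (nm^2) from the cited simulation literature; inputs, not
# hard-coded truth - override per LiposomeGeometry as needed.
DEFAULT_HEADGROUP_AREAS = {"MGDG": 0.62, "DGDG": 0.70, "SQDG": 0.66, "EPG": 0.64}

LDH_RS_NM = 4.3            # literature hydrodynamic radius of tetrameric LDH
DEFAULT_LIPOSOME_RADIUS_NM = 50.0    # 100 nm extrusion pore
DEFAULT_BILAYER_THICKNESS_NM = 4.0


@dataclass(frozen=True)
class LiposomeGeometry:
    lipid_fractions: dict[str, float] = field(
        default_factory=lambda: dict(ICMM_LIPID_FRACTIONS))
    headgroup_areas_nm2: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HEADGROUP_AREAS))
    radius_nm: float = DEFAULT_LIPOSOME_RADIUS_NM
    bilayer_thickness_nm: float = DEFAULT_BILAYER_THICKNESS_NM

    def __post_init__(self) -> None:
        if abs(sum(self.lipid_fractions.values()) - 1.0) > 1e-6:
            raise ValueError("lipid fractions must sum to 1")
        if self.radius_nm <= self.bilayer_thickness_nm:
            raise ValueError("liposome radius must exceed the bilayer thickness")
        if self.bilayer_thickness_nm <= 0:
            raise ValueError("bilayer thickness must be positive")
        for sp, f in self.lipid_fractions.items():
            if f < 0:
                raise ValueError("lipid fractions must be non-negative")
            if self.headgroup_areas_nm2.get(sp, 0) <= 0:
                raise ValueError(f"missing/invalid head-group area for {sp!r}")


def lipids_per_vesicle(geom: LiposomeGeometry) -> float:
    """n_l,tot = sum_l f_l * [4 pi R^2 + 4 pi (R - d_bl)^2] / a_l.

    Outer plus inner leaflet area of a spherical unilamellar vesicle divided
    by the composition-weighted per-lipid head-group area.
    """
    R = geom.radius_nm
    d = geom.bilayer_thickness_nm
    area = 4.0 * np.pi * R**2 + 4.0 * np.pi * (R - d) ** 2
    return float(sum(f * area / geom.headgroup_areas_nm2[sp]
                     for sp, f in geom.lipid_fractions.items()))


@dataclass(frozen=True)
class Protectant:
    concentration_mg_mL: float
    R_S_nm: float
    MW_g_mol: float

    def __post_init__(self) -> None:
        if min(self.concentration_mg_mL, self.R_S_nm, self.MW_g_mol) <= 0:
            raise ValueError("protectant parameters must be positive")

    @property
    def contact_area_nm2(self) -> float:
        return float(np.pi * self.R_S_nm**2)


@dataclass(frozen=True)
class ProteinTarget:
    concentration_mg_mL: float
    MW_g_mol: float
    R_S_nm: float = LDH_RS_NM


@dataclass(frozen=True)
class LiposomeTarget:
    lipid_concentration_mg_mL: float
    mean_lipid_MW_g_mol: float
    geometry: LiposomeGeometry = field(default_factory=LiposomeGeometry)


def surface_occupancy(protectant: Protectant,
                      target: ProteinTarget | LiposomeTarget) -> float:
    """Dimensionless surface occupancy of a protein or liposome target.

    Protein target:  c_P a_P MW_T / (a_T c_T MW_P).
    Liposome target: c_P a_P n_l,tot MW_lipid / (a_T c_lipid MW_P),
    with a_T the outer sphere area of the vesicle.
    """
    a_prot = protectant.contact_area_nm2
    if isinstance(target, ProteinTarget):
        if target.concentration_mg_mL <= 0:
            raise ValueError("target concentration must be positive")
        a_target = 4.0 * np.pi * target.R_S_nm**2
        return (protectant.concentration_mg_mL * a_prot * target.MW_g_mol
                / (a_target * target.concentration_mg_mL * protectant.MW_g_mol))
    if isinstance(target, LiposomeTarget):
        if target.lipid_concentration_mg_mL <= 0:
            raise ValueError("lipid concentration must be positive")
        n_tot = lipids_per_vesicle(target.geometry)
        a_target = 4.0 * np.pi * target.geometry.radius_nm**2
        return (protectant.concentration_mg_mL * a_prot * n_tot
                * target.mean_lipid_MW_g_mol
                / (a_target * target.lipid_concentration_mg_mL
                   * protectant.MW_g_mol))
    raise TypeError("target must be a ProteinTarget or LiposomeTarget")
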