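"""Closed-form design analysis for perfused parallel-plate culture chambers.

A chamber of height ``h`` perfused at flow rate ``Q`` washes cell-secreted
ligand downstream while the ligand simultaneously diffuses (diffusivity
``D_L``) and binds to cell-surface receptors on the floor. Three
dimensionless groups summarise the competition:

* Péclet number ``Pe = v_mean · h / D_L`` — convection vs. diffusion;
* Damköhler number ``Da = k_on · ρ_R · h / D_L`` — receptor binding vs.
  diffusion, with ``ρ_R`` the receptor surface density of a confluent
  monolayer (receptors of one cell spread over its projected disc);
* their ratio ``Pe/Da`` — convection vs. binding.

``Pe ≫ 1`` together with ``Pe/Da ≫ 1`` identifies the convection-dominated
regime in which perfusion can strip autocrine/paracrine ligands from the
culture before receptors recapture them. The module also reports the
plane-Poiseuille wall shear ``τ = 6µQ/(w·h²)`` (the biological constraint on
how fast one may perfuse) and surface-to-volume ratios used when comparing
chamber culture to dish culture.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from . import units


class InvalidParameterError(ValueError):
    """A physical parameter is outside its valid domain."""


class Regime(str, enum.Enum):
    """Transport regime classification for a chamber design point."""

    CONVECTION_DOMINATED = "convection_dominated"
    DIFFUSION_DOMINATED = "diffusion_dominated"
    REACTION_LIMITED = "reaction_limited"
    MIXED = "mixed"


@dataclass(frozen=True)
class ChamberGeometry:
    """Rectangular culture chamber, dimensions in µm.

    The analysis assumes parallel-plate flow (height small compared to
    width); a geometry with ``height > width`` is rejected.
    """

    height_um: float
    width_um: float
    length_um: float

    def __post_init__(self) -> None:
        for name in ("height_um", "width_um", "length_um"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.height_um > self.width_um:
            raise InvalidParameterError(
                "height > width violates the parallel-plate assumption"
            )

    @property
    def height_m(self) -> float:
        return units.um_to_m(self.height_um)

    @property
    def width_m(self) -> float:
        return units.um_to_m(self.width_um)

    @property
    def length_m(self) -> float:
        return units.um_to_m(self.length_um)


@dataclass(frozen=True)
class PerfusionSetting:
    """Pump flow rate (µL/hr) and medium viscosity (Pa·s, aqueous at 37 °C)."""

    flow_rate_ul_hr: float
    viscosity_pa_s: float = 1.0e-3

    def __post_init__(self) -> None:
        if self.flow_rate_ul_hr < 0:
            raise InvalidParameterError("flow_rate_ul_hr must be >= 0")
        if self.viscosity_pa_s <= 0:
            raise InvalidParameterError("viscosity_pa_s must be > 0")


#: sanity window for small-protein aqueous diffusivities, cm²/s
_D_WINDOW_CM2_S = (1e-9, 1e-4)


@dataclass(frozen=True)
class LigandSpec:
    """A secreted ligand: molecular weight (kDa) and diffusivity (cm²/s)."""

    mw_kda: float
    diffusivity_cm2_s: float

    def __post_init__(self) -> None:
        if self.mw_kda <= 0:
            raise InvalidParameterError("mw_kda must be > 0")
        lo, hi = _D_WINDOW_CM2_S
        if not (lo < self.diffusivity_cm2_s < hi):
            raise InvalidParameterError(
                f"diffusivity {self.diffusivity_cm2_s} cm²/s outside sanity "
                f"window ({lo}, {hi})"
            )

    @property
    def diffusivity_m2_s(self) -> float:
        return units.cm2_per_s_to_m2_per_s(self.diffusivity_cm2_s)


@dataclass(frozen=True)
class ReceptorSpec:
    """Cell-surface receptor kinetics: k_on (M⁻¹s⁻¹), copies/cell, cell radius (µm)."""

    kon_per_M_s: float
    receptors_per_cell: float
    cell_radius_um: float

    def __post_init__(self) -> None:
        if self.kon_per_M_s < 0:
            raise InvalidParameterError("kon_per_M_s must be >= 0")
        if self.receptors_per_cell < 0:
            raise InvalidParameterError("receptors_per_cell must be >= 0")
        if self.cell_radius_um <= 0:
            raise InvalidParameterError("cell_radius_um must be > 0")


@dataclass(frozen=True)
class DimensionlessSummary:
    """Design-point summary: velocity, Pe, Da, Pe/Da, wall shear, regime."""

    v_mean_mm_s: float
    peclet: float
    damkohler: float
    pe_over_da: float
    wall_shear_dyn_cm2: float
    regime: Regime


def mean_velocity(setting: PerfusionSetting, geom: ChamberGeometry) -> float:
    """Mean fluid velocity Q/(w·h) in the chamber, in mm/s."""
    q = units.ul_per_hr_to_m3_per_s(setting.flow_rate_ul_hr)
    area = geom.width_m * geom.height_m
    return units.m_to_mm(q / area)


def estimate_diffusivity(mw_kda: float, anchor_mw_kda: float = 20.0,
                         anchor_d_cm2_s: float = 1e-6) -> float:
    """Diffusivity (cm²/s) from molecular weight by Stokes–Einstein scaling.

    The hydrodynamic radius of a globular protein scales as MW^(1/3), so
    D ∝ MW^(-1/3); the estimate is anchored at a reference molecule.
    """
    if mw_kda <= 0 or anchor_mw_kda <= 0 or anchor_d_cm2_s <= 0:
        raise InvalidParameterError("molecular weights and diffusivity must be > 0")
    return anchor_d_cm2_s * (anchor_mw_kda / mw_kda) ** (1.0 / 3.0)


def peclet(v_mean_mm_s: float, geom: ChamberGeometry, ligand: LigandSpec) -> float:
    """Péclet number v_mean·h/D_L (dimensionless)."""
    if ligand.diffusivity_cm2_s <= 0:
        raise InvalidParameterError("diffusivity must be > 0")
    v = v_mean_mm_s * units.MM_TO_M
    return v * geom.height_m / ligand.diffusivity_m2_s


def receptor_areal_density(rec: ReceptorSpec) -> float:
    """Receptor surface density ρ_R in mol/m².

    Confluent-monolayer convention: the receptors of one cell are spread
    uniformly over its projected disc of radius ``cell_radius_um``.
    """
    r = units.um_to_m(rec.cell_radius_um)
    return rec.receptors_per_cell / (math.pi * r * r * units.AVOGADRO)


def damkohler(rec: ReceptorSpec, geom: ChamberGeometry, ligand: LigandSpec) -> float:
    """Damköhler number k_on·ρ_R·h/D_L (dimensionless)."""
    kon = units.kon_to_si(rec.kon_per_M_s)  # m³·mol⁻¹·s⁻¹
    rho = receptor_areal_density(rec)  # mol/m²
    return kon * rho * geom.height_m / ligand.diffusivity_m2_s


def uptake_velocity(rec: ReceptorSpec) -> float:
    """Effective floor uptake velocity k_on·ρ_R in m/s (used by the simulator)."""
    return units.kon_to_si(rec.kon_per_M_s) * receptor_areal_density(rec)


def pe_over_da(pe: float, da: float) -> float:
    """Ratio Pe/Da, convection vs. receptor binding."""
    if da == 0:
        raise ZeroDivisionError(
            "Da = 0 (reaction-free regime): Pe/Da is undefined"
        )
    return pe / da


def wall_shear(setting: PerfusionSetting, geom: ChamberGeometry,
               cell_factor: float = 1.0) -> float:
    """Wall shear stress in dyn/cm².

    Plane-Poiseuille wall shear 6µQ/(w·h²), times an optional multiplicative
    correction for flow perturbation by attached cells (default 1.0, i.e.
    the bare-wall value).
    """
    if cell_factor <= 0:
        raise InvalidParameterError("cell_factor must be > 0")
    q = units.ul_per_hr_to_m3_per_s(setting.flow_rate_ul_hr)
    tau_pa = 6.0 * setting.viscosity_pa_s * q / (geom.width_m * geom.height_m ** 2)
    return cell_factor * units.pa_to_dyn_cm2(tau_pa)


def surface_to_volume_chamber(geom: ChamberGeometry) -> float:
    """Culture-surface-to-media-volume ratio of the chamber, in 1/mm.

    The floor is the sole culture surface, so SA/V = (w·L)/(w·L·h) = 1/h.
    """
    return 1.0 / (geom.height_um * units.UM_TO_M / units.MM_TO_M)


def surface_to_volume_dish(growth_area_cm2: float, media_volume_ml: float) -> float:
    """SA/V of a conventional dish (growth area / media volume), in 1/mm."""
    if media_volume_ml <= 0:
        raise InvalidParameterError("media_volume_ml must be > 0")
    if growth_area_cm2 <= 0:
        raise InvalidParameterError("growth_area_cm2 must be > 0")
    area_mm2 = growth_area_cm2 * 100.0
    volume_mm3 = media_volume_ml * 1000.0
    return area_mm2 / volume_mm3


def classify_regime(pe: float, da: float, pe_threshold: float = 10.0,
                    ratio_threshold: float = 10.0) -> Regime:
    """Classify the transport regime of a design point.

    Convection-dominated requires both strong convection relative to
    diffusion (Pe above ``pe_threshold``) and relative to binding (Pe/Da
    above ``ratio_threshold``). Otherwise the slower of diffusion and
    reaction labels the regime: Da < 1 means binding is the bottleneck seen
    from diffusion's side, so transport is diffusion-dominated; Da > 1 is
    reaction-limited; ambiguous combinations are "mixed".
    """
    if pe < 0 or da < 0:
        raise InvalidParameterError("Pe and Da must be >= 0")
    ratio = pe / da if da > 0 else math.inf
    if pe > pe_threshold and ratio > ratio_threshold:
        return Regime.CONVECTION_DOMINATED
    if da < 1.0:
        return Regime.DIFFUSION_DOMINATED
    if pe <= pe_threshold and da > 1.0:
        return Regime.REACTION_LIMITED
    return Regime.MIXED


def summarize(setting: PerfusionSetting, geom: ChamberGeometry,
              ligand: LigandSpec, rec: ReceptorSpec,
              cell_factor: float = 1.0) -> DimensionlessSummary:
    """Full dimensionless summary of a chamber design point."""
    v = mean_velocity(setting, geom)
    pe = peclet(v, geom, ligand)
    da = damkohler(rec, geom, ligand)
    ratio = pe_over_da(pe, da) if da > 0 else math.inf
    tau = wall_shear(setting, geom, cell_factor)
    return DimensionlessSummary(
        v_mean_mm_s=v,
        peclet=pe,
        damkohler=da,
        pe_over_da=ratio,
        wall_shear_dyn_cm2=tau,
        regime=classify_regime(pe, da),
    )


def reference_design_point() -> tuple[PerfusionSetting, ChamberGeometry, LigandSpec, ReceptorSpec]:
    """Reference design point of the platform this package models.

    250 µm-high × 13 mm-long × 1.25 mm-wide chambers perfused at 33 µL/hr
    with a ~20 kDa ligand (D_L = 1e-6 cm²/s, the conservative end of the
    scaling estimate) binding to 10⁴ receptors per 10 µm-radius cell at
    k_on = 1e6 M⁻¹s⁻¹.
    """
    return (
        PerfusionSetting(flow_rate_ul_hr=33.0),
        ChamberGeometry(height_um=250.0, width_um=1250.0, length_um=13000.0),
        LigandSpec(mw_kda=20.0, diffusivity_cm2_s=1e-6),
        ReceptorSpec(kon_per_M_s=1e6, receptors_per_cell=1e4, cell_radius_um=10.0),
    )
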