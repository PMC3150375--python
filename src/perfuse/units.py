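"""Unit conversions between SI internals and the bench units used at the interface.

All physics inside the package is computed in SI (m, s, mol, Pa). Public
interfaces accept and report the units a microfluidics bench uses: µm for
chamber dimensions, µL/hr for syringe-pump flow rates, cm²/s for ligand
diffusivities, M⁻¹s⁻¹ for association rates, mm/s for velocities and
dyn/cm² for shear stress.
"""

from __future__ import annotations

AVOGADRO = 6.02214076e23  # 1/mol

# length
UM_TO_M = 1e-6
MM_TO_M = 1e-3

# flow rate
UL_PER_HR_TO_M3_PER_S = 1e-9 / 3600.0

# diffusivity
CM2_PER_S_TO_M2_PER_S = 1e-4

# association rate: 1 M⁻¹s⁻¹ = 1 L·mol⁻¹·s⁻¹ = 1e-3 m³·mol⁻¹·s⁻¹
PER_M_S_TO_M3_PER_MOL_S = 1e-3

# stress: 1 Pa = 10 dyn/cm²
PA_TO_DYN_PER_CM2 = 10.0


def um_to_m(x: float) -> float:
    return x * UM_TO_M


def m_to_mm(x: float) -> float:
    return x / MM_TO_M


def ul_per_hr_to_m3_per_s(q: float) -> float:
    return q * UL_PER_HR_TO_M3_PER_S


def cm2_per_s_to_m2_per_s(d: float) -> float:
    return d * CM2_PER_S_TO_M2_PER_S


def kon_to_si(kon_per_M_s: float) -> float:
    """M⁻¹s⁻¹ → m³·mol⁻¹·s⁻¹."""
    return kon_per_M_s * PER_M_S_TO_M3_PER_MOL_S


def pa_to_dyn_cm2(tau: float) -> float:
    return tau * PA_TO_DYN_PER_CM2
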