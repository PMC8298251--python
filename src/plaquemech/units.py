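"""Centralized unit conventions and conversions.

Coordinates are in mm, areas in mm^2; solid stresses and moduli in kPa;
pressures are stated in mmHg at the interface and converted to kPa for the
solver; wall shear stress is reported in dyn/cm^2 (1 kPa = 1e4 dyn/cm^2);
blood viscosity in Poise (dyn*s/cm^2).
"""

MMHG_TO_KPA = 0.133322
KPA_TO_DYN_CM2 = 1.0e4
MM_TO_CM = 0.1


def mmhg_to_kpa(p_mmhg: float) -> float:
    return p_mmhg * MMHG_TO_KPA


def kpa_to_dyn_cm2(s_kpa: float) -> float:
    return s_kpa * KPA_TO_DYN_CM2
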