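"""Unit conversions between SI (internal) and the reporting units (cm, mmHg, mL, s).

All solver internals are SI; every public surface (configuration files, probe
CSVs, metrics) uses the clinical units. Conversions here are the single source
of truth so that round-trips invert to machine precision.
"""

from __future__ import annotations

MMHG_PA: float = 133.322387415  # 1 mmHg in Pa
ML_M3: float = 1e-6             # 1 mL in m^3
CM_M: float = 1e-2              # 1 cm in m

#: hydraulic resistance, 1 mmHg.s/mL in Pa.s/m^3
RES_MMHG_S_ML: float = MMHG_PA / ML_M3


def mmhg_to_pa(p: float) -> float:
    return p * MMHG_PA


def pa_to_mmhg(p: float) -> float:
    return p / MMHG_PA


def ml_to_m3(v: float) -> float:
    return v * ML_M3


def m3_to_ml(v: float) -> float:
    return v / ML_M3


def cm_to_m(x: float) -> float:
    return x * CM_M


def m_to_cm(x: float) -> float:
    return x / CM_M


def resistance_si_to_clinical(r_pa_s_m3: float) -> float:
    """Pa.s/m^3 -> mmHg.s/mL."""
    return r_pa_s_m3 / RES_MMHG_S_ML


def resistance_clinical_to_si(r_mmhg_s_ml: float) -> float:
    """mmHg.s/mL -> Pa.s/m^3."""
    return r_mmhg_s_ml * RES_MMHG_S_ML
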