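"""Unit conversions between internal SI and conventional reporting units.

All waveform-level computation in this package is done in SI (m, s, m/s,
m², m³/s, Pa, kg/m³) so that the flow–area (QA) loop slope is dimensionally
a velocity.  Conversions to the units used in vascular ultrasound reports
(mm, mm², mm/s, mL/min, beats/min, kPa, g/mL) happen only at I/O
boundaries.
"""

from __future__ import annotations

#: metres per millimetre
M_PER_MM = 1e-3
#: m² per mm²
M2_PER_MM2 = 1e-6
#: m³/s per mL/min
M3S_PER_MLMIN = 1e-6 / 60.0
#: kg/m³ per g/mL
KGM3_PER_GML = 1000.0


def mm_to_m(x):
    return x * M_PER_MM


def m_to_mm(x):
    return x / M_PER_MM


def mm2_to_m2(x):
    return x * M2_PER_MM2


def m2_to_mm2(x):
    return x / M2_PER_MM2


def mlmin_to_m3s(x):
    return x * M3S_PER_MLMIN


def m3s_to_mlmin(x):
    return x / M3S_PER_MLMIN


def mms_to_ms(x):
    """mm/s to m/s."""
    return x * 1e-3


def ms_to_mms(x):
    """m/s to mm/s."""
    return x * 1e3


def gml_to_kgm3(x):
    return x * KGM3_PER_GML


def pa_to_kpa(x):
    return x * 1e-3


def bpm_to_hz(x):
    return x / 60.0


def hz_to_bpm(x):
    return x * 60.0
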