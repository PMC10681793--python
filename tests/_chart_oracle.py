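"""Independent brute-force transcription of the NEWS2 chart.

Deliberately written as literal two-sided band conditions, one line per
printed chart cell, so it shares no band logic with the production lookup.
Returns None when a (rounded) value falls in no printed band, which lets the
grid tests detect gaps as well as disagreements. The rounding convention
(chart precision, ties away from zero) is part of the scoring definition
and therefore shared with production by design.
"""

import math


def oracle_round(value: float, decimals: int) -> float:
    f = 10.0 ** decimals
    return math.floor(value * f + 0.5) / f  # inputs are non-negative


def oracle_score(parameter: str, value: float, spo2_scale: str | None = None):
    decimals = 1 if parameter == "temperature" else 0
    v = oracle_round(float(value), decimals)

    if parameter == "respiration_rate":
        if v <= 8:
            return 3
        if 9 <= v <= 11:
            return 1
        if 12 <= v <= 20:
            return 0
        if 21 <= v <= 24:
            return 2
        if v >= 25:
            return 3
        return None

    if parameter == "spo2":
        if spo2_scale == "scale1":
            if v <= 91:
                return 3
            if 92 <= v <= 93:
                return 2
            if 94 <= v <= 95:
                return 1
            if v >= 96:
                return 0
            return None
        if spo2_scale == "scale2":
            if v <= 83:
                return 3
            if 84 <= v <= 85:
                return 2
            if 86 <= v <= 87:
                return 1
            if 88 <= v <= 92:
                return 0
            if v >= 93:
                return 0  # room air above the printed scale-2 bands
            return None
        raise ValueError("spo2_scale required")

    if parameter == "systolic_bp":
        if v <= 90:
            return 3
        if 91 <= v <= 100:
            return 2
        if 101 <= v <= 110:
            return 1
        if 111 <= v <= 219:
            return 0
        if v >= 220:
            return 3
        return None

    if parameter == "pulse_rate":
        if v <= 40:
            return 3
        if 41 <= v <= 50:
            return 1
        if 51 <= v <= 90:
            return 0
        if 91 <= v <= 110:
            return 1
        if 111 <= v <= 130:
            return 2
        if v >= 131:
            return 3
        return None

    if parameter == "temperature":
        if v <= 35.0:
            return 3
        if 35.1 <= v <= 36.0:
            return 1
        if 36.1 <= v <= 38.0:
            return 0
        if 38.1 <= v <= 39.0:
            return 1
        if v >= 39.1:
            return 2
        return None

    raise ValueError(f"unknown parameter {parameter!r}")
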