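"""National Early Warning Score 2 (NEWS2) banded scoring.

NEWS2 is the Royal College of Physicians' chart for grading acute clinical
deterioration: each routinely measured physiological parameter is mapped to
an integer band score in {0, 1, 2, 3}, the band scores are summed into an
aggregate, and the aggregate (together with any single extreme band) is
mapped to a clinical-risk tier that triggers an escalating response.

This implementation targets *ambulatory remote monitoring of noncritical
patients*: consciousness is fixed to ``alert`` and the patient breathes room
air, so those two chart rows always contribute 0 and only the five measured
parameters — respiration rate, oxygen saturation, systolic blood pressure,
pulse rate and body temperature — are scored. Patients on supplemental
oxygen or with altered consciousness are out of scope and such inputs are
rejected rather than silently mis-scored.

Band boundaries are printed at integer precision for rates and pressures and
0.1 °C precision for temperature. Raw measurements are rounded to that
precision (half away from zero) before lookup, which makes the printed bands
exhaustive over the reals: e.g. a respiration rate of 8.4 rounds to 8 and
scores 3, while 8.6 rounds to 9 and scores 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional


class Spo2Scale(str, Enum):
    """Which SpO2 row of the chart applies.

    Scale 2 is used for patients with hypercapnic respiratory failure whose
    target saturations are shifted downwards.
    """

    SCALE1 = "scale1"
    SCALE2 = "scale2"


class ClinicalRisk(str, Enum):
    LOW = "low"
    LOW_MEDIUM = "low_medium"
    MEDIUM = "medium"
    HIGH = "high"


#: Severity ordering of the risk tiers (index = rank).
RISK_ORDER: tuple[ClinicalRisk, ...] = (
    ClinicalRisk.LOW,
    ClinicalRisk.LOW_MEDIUM,
    ClinicalRisk.MEDIUM,
    ClinicalRisk.HIGH,
)


def risk_rank(risk: ClinicalRisk) -> int:
    """Integer severity rank of a clinical-risk tier (low=0 … high=3)."""
    return RISK_ORDER.index(ClinicalRisk(risk))


#: The five parameters scored in this system, in chart order.
SCORED_PARAMETERS: tuple[str, ...] = (
    "respiration_rate",
    "spo2",
    "systolic_bp",
    "pulse_rate",
    "temperature",
)

#: Physically plausible input ranges; values outside are measurement errors
#: and rejected rather than scored. (lo, hi, lo_inclusive)
PHYSICAL_RANGES: dict[str, tuple[float, float, bool]] = {
    "respiration_rate": (0.0, 80.0, False),
    "spo2": (0.0, 100.0, True),
    "systolic_bp": (0.0, 300.0, False),
    "pulse_rate": (0.0, 350.0, False),
    "temperature": (25.0, 45.0, True),
}

#: The chart truncates SpO2 scale 2 at its "88-92" score-0 band; for a
#: patient breathing room air, saturations of 93% and above also score 0
#: (the elevated-saturation penalties on scale 2 apply only on oxygen).
SPO2_SCALE2_ON_AIR_HIGH_SCORE: int = 0


def _round_half_away(value: float, decimals: int = 0) -> float:
    """Round to `decimals` places with ties away from zero."""
    factor = 10.0 ** decimals
    scaled = abs(value) * factor
    rounded = math.floor(scaled + 0.5) / factor
    return rounded if value >= 0 else -rounded


def _check_range(parameter: str, value: float) -> None:
    lo, hi, lo_inclusive = PHYSICAL_RANGES[parameter]
    if not math.isfinite(value):
        raise ValueError(f"{parameter} must be finite, got {value!r}")
    ok = (value >= lo if lo_inclusive else value > lo) and value <= hi
    if not ok:
        bracket = "[" if lo_inclusive else "("
        raise ValueError(
            f"{parameter} out of {bracket}{lo}, {hi}]: {value}"
        )


# --- per-parameter band lookups (value already rounded to chart precision) ---

def _score_respiration(r: float) -> int:
    if r <= 8:
        return 3
    if r <= 11:
        return 1
    if r <= 20:
        return 0
    if r <= 24:
        return 2
    return 3


def _score_spo2_scale1(s: float) -> int:
    if s <= 91:
        return 3
    if s <= 93:
        return 2
    if s <= 95:
        return 1
    return 0


def _score_spo2_scale2(s: float) -> int:
    if s <= 83:
        return 3
    if s <= 85:
        return 2
    if s <= 87:
        return 1
    if s <= 92:
        return 0
    return SPO2_SCALE2_ON_AIR_HIGH_SCORE


def _score_systolic_bp(p: float) -> int:
    if p <= 90:
        return 3
    if p <= 100:
        return 2
    if p <= 110:
        return 1
    if p <= 219:
        return 0
    return 3


def _score_pulse(p: float) -> int:
    if p <= 40:
        return 3
    if p <= 50:
        return 1
    if p <= 90:
        return 0
    if p <= 110:
        return 1
    if p <= 130:
        return 2
    return 3


def _score_temperature(t: float) -> int:
    if t <= 35.0:
        return 3
    if t <= 36.0:
        return 1
    if t <= 38.0:
        return 0
    if t <= 39.0:
        return 1
    return 2


def score_parameter(
    parameter: str,
    value: float,
    spo2_scale: Optional[Spo2Scale | str] = None,
) -> int:
    """Band score in {0, 1, 2, 3} for a single physiological parameter.

    Parameters
    ----------
    parameter
        One of :data:`SCORED_PARAMETERS`.
    value
        The measurement, in the parameter's natural units (breaths/min,
        %, mmHg, bpm, °C). Rounded to the chart's printed precision
        before lookup.
    spo2_scale
        Required when ``parameter == "spo2"``; must be omitted otherwise.
    """
    if parameter not in SCORED_PARAMETERS:
        raise ValueError(f"unknown scored parameter: {parameter!r}")
    if parameter == "spo2":
        if spo2_scale is None:
            raise ValueError("spo2_scale is required when scoring spo2")
        spo2_scale = Spo2Scale(spo2_scale)
    elif spo2_scale is not None:
        raise ValueError(f"spo2_scale does not apply to {parameter!r}")

    _check_range(parameter, float(value))
    decimals = 1 if parameter == "temperature" else 0
    v = _round_half_away(float(value), decimals)

    if parameter == "respiration_rate":
        return _score_respiration(v)
    if parameter == "spo2":
        if spo2_scale is Spo2Scale.SCALE1:
            return _score_spo2_scale1(v)
        return _score_spo2_scale2(v)
    if parameter == "systolic_bp":
        return _score_systolic_bp(v)
    if parameter == "pulse_rate":
        return _score_pulse(v)
    return _score_temperature(v)


@dataclass
class VitalSigns:
    """One patient's measured physiological parameters at one time point.

    The five scored parameters are optional at construction so that missing
    measurements can be detected and reported by :func:`compute_news2` (the
    scorer never imputes). Consciousness and air/oxygen status are fixed to
    their noncritical-patient values; any other value is rejected.
    """

    respiration_rate: Optional[float] = None
    spo2: Optional[float] = None
    systolic_bp: Optional[float] = None
    pulse_rate: Optional[float] = None
    temperature: Optional[float] = None
    spo2_scale: Spo2Scale = Spo2Scale.SCALE1
    consciousness: str = "alert"
    air_or_oxygen: str = "air"
    diastolic_bp: Optional[float] = None  # carried for records, never scored

    def __post_init__(self) -> None:
        self.spo2_scale = Spo2Scale(self.spo2_scale)
        if self.consciousness != "alert":
            raise ValueError(
                "only consciousness='alert' is supported (noncritical "
                f"monitoring), got {self.consciousness!r}"
            )
        if self.air_or_oxygen != "air":
            raise ValueError(
                "only air_or_oxygen='air' is supported (noncritical "
                f"monitoring), got {self.air_or_oxygen!r}"
            )
        for name in SCORED_PARAMETERS:
            v = getattr(self, name)
            if v is not None:
                _check_range(name, float(v))
        if self.diastolic_bp is not None and not 0 < self.diastolic_bp <= 300:
            raise ValueError(f"diastolic_bp out of (0, 300]: {self.diastolic_bp}")

    def missing_parameters(self) -> list[str]:
        return [p for p in SCORED_PARAMETERS if getattr(self, p) is None]


@dataclass(frozen=True)
class News2Result:
    """Per-parameter band scores, their sum, and the clinical-risk tier."""

    component_scores: Mapping[str, int]
    aggregate: int
    clinical_risk: ClinicalRisk


def classify_risk(
    aggregate: int, component_scores: Mapping[str, int]
) -> ClinicalRisk:
    """Map an aggregate score (plus its components) to the clinical-risk tier.

    Tiers are increasing in severity: an aggregate of 7 or more is *high*,
    5–6 is *medium*, and an aggregate of at most 4 is *low* unless any single
    parameter scored 3, in which case it is *low-medium* (a single extreme
    value warrants review even when the sum is unremarkable).
    """
    aggregate = int(aggregate)
    total = sum(int(s) for s in component_scores.values())
    if aggregate != total:
        raise ValueError(
            f"aggregate {aggregate} inconsistent with component sum {total}"
        )
    if aggregate >= 7:
        return ClinicalRisk.HIGH
    if aggregate >= 5:
        return ClinicalRisk.MEDIUM
    if any(int(s) == 3 for s in component_scores.values()):
        return ClinicalRisk.LOW_MEDIUM
    return ClinicalRisk.LOW


def compute_news2(vitals: VitalSigns) -> News2Result:
    """Score all five parameters, sum them, and classify the clinical risk.

    Raises ``ValueError`` naming any missing scored parameter; imputation,
    when wanted, happens upstream of this function.
    """
    missing = vitals.missing_parameters()
    if missing:
        raise ValueError(f"missing scored parameter(s): {', '.join(missing)}")
    scores = {
        name: score_parameter(
            name,
            getattr(vitals, name),
            spo2_scale=vitals.spo2_scale if name == "spo2" else None,
        )
        for name in SCORED_PARAMETERS
    }
    aggregate = sum(scores.values())
    return News2Result(
        component_scores=scores,
        aggregate=aggregate,
        clinical_risk=classify_risk(aggregate, scores),
    )
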