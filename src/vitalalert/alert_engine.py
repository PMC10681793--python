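"""Fusion of three abnormality indicators into a four-level alert.

A single thresholded vital sign generates many false alarms and drives alarm
fatigue. The fusion rule here instead counts how many of three *independent*
indicators flag the patient as abnormal:

1. a trained binary risk classifier predicting normal/abnormal status,
2. the NEWS2 aggregate exceeding a threshold (default: strictly above 7),
3. the resting heart rate leaving the normal 60–100 bpm range.

Each indicator contributes 0 or 1, so the aggregated alert score lies in
{0, 1, 2, 3} and maps one-to-one onto the urgency colours green, yellow,
orange and red. Alerts are raised only at orange or red — i.e. when at
least two independent indicators agree the patient is abnormal.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class AlertLevel(str, Enum):
    GREEN = "green"
    YELLOW = "yellow"
    ORANGE = "orange"
    RED = "red"


LEVEL_BY_SCORE: dict[int, AlertLevel] = {
    0: AlertLevel.GREEN,
    1: AlertLevel.YELLOW,
    2: AlertLevel.ORANGE,
    3: AlertLevel.RED,
}

#: Severity ordering of the urgency levels (index = rank).
LEVEL_ORDER: tuple[AlertLevel, ...] = (
    AlertLevel.GREEN,
    AlertLevel.YELLOW,
    AlertLevel.ORANGE,
    AlertLevel.RED,
)


@dataclass(frozen=True)
class AlertConfig:
    """Thresholds of the fusion rule.

    ``news2_strict=True`` means the NEWS2 indicator fires only for an
    aggregate strictly above ``news2_threshold``; set it to False to fire at
    the threshold itself (the high-clinical-risk boundary).
    """

    news2_threshold: int = 7
    news2_strict: bool = True
    hr_low: float = 60.0
    hr_high: float = 100.0

    def __post_init__(self) -> None:
        if not 0 <= self.news2_threshold <= 15:
            raise ValueError(
                f"news2_threshold out of [0, 15]: {self.news2_threshold}"
            )
        if not self.hr_low < self.hr_high:
            raise ValueError(
                f"hr_low must be below hr_high, got {self.hr_low} >= {self.hr_high}"
            )


DEFAULT_ALERT_CONFIG = AlertConfig()


@dataclass(frozen=True)
class AlertResult:
    """The three component indicators and their fused alert."""

    classifier_abnormal: bool
    news2_trigger: bool
    hr_abnormal: bool
    alert_score: int
    level: AlertLevel
    alert_raised: bool


def hr_flag(heart_rate: float, config: AlertConfig = DEFAULT_ALERT_CONFIG) -> bool:
    """True iff the resting heart rate is abnormal.

    Rates below ``hr_low`` or above ``hr_high`` are abnormal; both bounds
    are themselves normal (60 ≤ HR ≤ 100 is the normal range).
    """
    if not heart_rate > 0:
        raise ValueError(f"heart rate must be positive, got {heart_rate}")
    return heart_rate < config.hr_low or heart_rate > config.hr_high


def news2_trigger(
    news2_aggregate: int, config: AlertConfig = DEFAULT_ALERT_CONFIG
) -> bool:
    """True iff the NEWS2 aggregate fires the alert component."""
    aggregate = int(news2_aggregate)
    if not 0 <= aggregate <= 15:
        raise ValueError(f"NEWS2 aggregate out of [0, 15]: {news2_aggregate}")
    if config.news2_strict:
        return aggregate > config.news2_threshold
    return aggregate >= config.news2_threshold


def compute_alert(
    classifier_abnormal: bool,
    news2_aggregate: int,
    heart_rate: float,
    config: AlertConfig = DEFAULT_ALERT_CONFIG,
) -> AlertResult:
    """Fuse the three indicators into the aggregated alert.

    Each true indicator adds one to the alert score; the score maps to the
    urgency level (0→green, 1→yellow, 2→orange, 3→red) and an alert is
    raised for orange or red.
    """
    news2_fired = news2_trigger(news2_aggregate, config)
    hr_fired = hr_flag(heart_rate, config)
    score = int(bool(classifier_abnormal)) + int(news2_fired) + int(hr_fired)
    level = LEVEL_BY_SCORE[score]
    return AlertResult(
        classifier_abnormal=bool(classifier_abnormal),
        news2_trigger=news2_fired,
        hr_abnormal=hr_fired,
        alert_score=score,
        level=level,
        alert_raised=level in (AlertLevel.ORANGE, AlertLevel.RED),
    )
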