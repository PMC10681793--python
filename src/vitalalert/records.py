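"""Patient records: formats, validation, BMI, and the batch alert pipeline.

A patient record carries identification and anthropometrics plus one set of
vital-sign measurements and the blood-sugar reading. Records round-trip
through CSV (UTF-8, comma-separated, mandatory header, '.' decimal) and JSON
(a list of objects); column names are the snake_case field names.
Temperatures are Celsius throughout — there is no unit auto-detection.

``run_pipeline`` composes the full alerting path per record: NEWS2 scoring →
classifier prediction → resting-heart-rate flag → alert fusion, collecting
per-level counts and reporting (rather than aborting on) per-record errors.
"""

from __future__ import annotations

import json
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alert_engine import (
    DEFAULT_ALERT_CONFIG,
    AlertConfig,
    AlertLevel,
    AlertResult,
    compute_alert,
)
from .news2 import News2Result, Spo2Scale, VitalSigns, compute_news2
from .risk_model import FittedModel

HEIGHT_RANGE_CM = (50.0, 250.0)  # exclusive bounds
WEIGHT_RANGE_KG = (20.0, 300.0)

MEAL_STATUSES = ("premeal", "postmeal", "unknown")
LABELS = ("normal", "abnormal")

#: Columns that must be present in a record file.
REQUIRED_COLUMNS = (
    "patient_id",
    "age",
    "sex",
    "height",
    "weight",
    "respiration_rate",
    "spo2",
    "systolic_bp",
    "pulse_rate",
    "temperature",
    "blood_sugar",
)

#: Columns that may be present.
OPTIONAL_COLUMNS = ("diastolic_bp", "spo2_scale", "meal_status", "label")


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index, kg/m², from weight (kg) and height (cm).

    Standard formula weight / height², reported to 4 significant figures.
    """
    if not WEIGHT_RANGE_KG[0] < weight < WEIGHT_RANGE_KG[1]:
        raise ValueError(f"weight out of ({WEIGHT_RANGE_KG[0]}, {WEIGHT_RANGE_KG[1]}) kg: {weight}")
    if not HEIGHT_RANGE_CM[0] < height < HEIGHT_RANGE_CM[1]:
        raise ValueError(f"height out of ({HEIGHT_RANGE_CM[0]}, {HEIGHT_RANGE_CM[1]}) cm: {height}")
    bmi = weight / (height / 100.0) ** 2
    return float(f"{bmi:.4g}")


@dataclass
class PatientRecord:
    """One patient's demographics, anthropometrics, and vital signs."""

    patient_id: str
    age: float
    sex: str
    height: float  # cm
    weight: float  # kg
    respiration_rate: float
    spo2: float
    systolic_bp: float
    pulse_rate: float
    temperature: float
    blood_sugar: float  # mg/dL
    diastolic_bp: Optional[float] = None
    spo2_scale: str = "scale1"
    meal_status: str = "unknown"
    label: Optional[str] = None

    def validation_errors(self) -> list[str]:
        """All invariant violations, as human-readable reasons."""
        reasons: list[str] = []
        if not isinstance(self.patient_id, str) or not self.patient_id.strip():
            reasons.append("patient_id must be a non-empty string")
        if not 0 < self.age < 130:
            reasons.append(f"age out of (0, 130): {self.age}")
        if not isinstance(self.sex, str) or not self.sex.strip():
            reasons.append("sex must be a non-empty string")
        if not HEIGHT_RANGE_CM[0] < self.height < HEIGHT_RANGE_CM[1]:
            reasons.append(f"height out of (50, 250) cm: {self.height}")
        if not WEIGHT_RANGE_KG[0] < self.weight < WEIGHT_RANGE_KG[1]:
            reasons.append(f"weight out of (20, 300) kg: {self.weight}")
        if self.meal_status not in MEAL_STATUSES:
            reasons.append(f"meal_status not in {MEAL_STATUSES}: {self.meal_status!r}")
        if self.label is not None and self.label not in LABELS:
            reasons.append(f"label not in {LABELS}: {self.label!r}")
        if not 0 <= self.spo2 <= 100:
            reasons.append(f"spo2 out of [0,100]: {self.spo2}")
        else:
            try:
                self.vitals()
            except ValueError as exc:
                reasons.append(str(exc))
        return reasons

    def vitals(self) -> VitalSigns:
        return VitalSigns(
            respiration_rate=self.respiration_rate,
            spo2=self.spo2,
            systolic_bp=self.systolic_bp,
            pulse_rate=self.pulse_rate,
            temperature=self.temperature,
            spo2_scale=Spo2Scale(self.spo2_scale),
            diastolic_bp=self.diastolic_bp,
        )

    @property
    def bmi(self) -> float:
        return compute_bmi(self.weight, self.height)


_FLOAT_FIELDS = (
    "age",
    "height",
    "weight",
    "respiration_rate",
    "spo2",
    "systolic_bp",
    "pulse_rate",
    "temperature",
    "blood_sugar",
    "diastolic_bp",
)


@dataclass
class RejectedRow:
    row: int  # 0-based data-row index in the source file
    patient_id: Optional[str]
    reason: str


@dataclass
class ReadResult:
    records: list[PatientRecord]
    rejects: list[RejectedRow] = field(default_factory=list)


def _record_from_mapping(raw: dict) -> PatientRecord:
    known = {f.name for f in fields(PatientRecord)}
    kwargs = {}
    for key, value in raw.items():
        if key not in known:
            continue
        if value is None or (isinstance(value, float) and np.isnan(value)):
            value = None
        elif key in _FLOAT_FIELDS:
            value = float(value)
        elif key == "patient_id" or isinstance(value, str):
            value = str(value).strip()
        kwargs[key] = value
    if kwargs.get("meal_status") is None:
        kwargs["meal_status"] = "unknown"
    if kwargs.get("spo2_scale") is None:
        kwargs["spo2_scale"] = "scale1"
    return PatientRecord(**kwargs)


def read_records(
    path: str | Path, fmt: Optional[str] = None, strict: bool = False
) -> ReadResult:
    """Read and validate patient records from CSV or JSON.

    Rows violating an invariant are rejected with a reason and the valid
    rows kept; ``strict=True`` instead raises on the first bad row. Missing
    required columns or duplicate patient ids raise; unknown columns warn.
    """
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    if fmt not in ("csv", "json"):
        raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'json'")

    if fmt == "csv":
        try:
            frame = pd.read_csv(path, dtype={"patient_id": str})
        except pd.errors.EmptyDataError:
            warnings.warn(f"{path} is empty; no records read")
            return ReadResult(records=[])
        raws = frame.to_dict(orient="records")
        columns = set(frame.columns)
    else:
        payload = json.loads(path.read_text(encoding="utf-8") or "[]")
        if not isinstance(payload, list):
            raise ValueError("JSON record file must contain a list of objects")
        raws = payload
        columns = set().union(*(r.keys() for r in raws)) if raws else set()

    if not raws:
        warnings.warn(f"{path} contains no records")
        return ReadResult(records=[])

    missing_cols = [c for c in REQUIRED_COLUMNS if c not in columns]
    if missing_cols:
        raise ValueError(f"missing required column(s): {missing_cols}")
    unknown = columns - set(REQUIRED_COLUMNS) - set(OPTIONAL_COLUMNS)
    if unknown:
        warnings.warn(f"ignoring unknown column(s): {sorted(unknown)}")

    records: list[PatientRecord] = []
    rejects: list[RejectedRow] = []
    seen_ids: set[str] = set()
    for i, raw in enumerate(raws):
        pid = raw.get("patient_id")
        pid = str(pid).strip() if pid is not None else None
        try:
            record = _record_from_mapping(raw)
            reasons = record.validation_errors()
            if reasons:
                raise ValueError("; ".join(reasons))
        except (ValueError, TypeError) as exc:
            if strict:
                raise ValueError(f"row {i}: {exc}") from exc
            rejects.append(RejectedRow(row=i, patient_id=pid, reason=str(exc)))
            continue
        if record.patient_id in seen_ids:
            raise ValueError(f"duplicate patient_id {record.patient_id!r} at row {i}")
        seen_ids.add(record.patient_id)
        records.append(record)
    return ReadResult(records=records, rejects=rejects)


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    cols = [f.name for f in fields(PatientRecord)]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)


def write_records(
    records: Sequence[PatientRecord], path: str | Path, fmt: Optional[str] = None
) -> None:
    """Write records as CSV or JSON (the inverse of :func:`read_records`)."""
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    frame = records_to_frame(records)
    if fmt == "csv":
        frame.to_csv(path, index=False)
    elif fmt == "json":
        payload = frame.to_dict(orient="records")
        for row in payload:  # NaN -> null for optional fields
            for k, v in row.items():
                if isinstance(v, float) and np.isnan(v):
                    row[k] = None
        path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'json'")


def records_to_features(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Model feature table (plus 0/1 label where present) from records.

    BMI is computed from weight and height; the recorded pulse rate is the
    heart-rate feature.
    """
    rows = []
    for r in records:
        row = {
            "age": r.age,
            "bmi": r.bmi,
            "heart_rate": r.pulse_rate,
            "systolic_bp": r.systolic_bp,
            "resp_rate": r.respiration_rate,
            "temperature": r.temperature,
            "spo2": r.spo2,
            "blood_sugar": r.blood_sugar,
        }
        if r.label is not None:
            row["label"] = 1 if r.label == "abnormal" else 0
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_to_records(
    cohort: pd.DataFrame, seed: int = 0, id_prefix: str = "P"
) -> list[PatientRecord]:
    """Dress a synthetic feature table up as full patient records.

    Identifiers and sex are synthesized; height is drawn around 165 cm and
    clamped so that the back-computed weight (from the generated BMI) stays
    in range — ``compute_bmi(weight, height)`` then recovers the BMI.
    """
    rng = np.random.default_rng(seed)
    n = len(cohort)
    heights = np.clip(rng.normal(165.0, 9.0, size=n), 145.0, 195.0)
    sexes = rng.choice(["female", "male"], size=n)
    records = []
    for i, (_, row) in enumerate(cohort.iterrows()):
        bmi = float(row["bmi"])
        h = float(heights[i])
        h = min(h, math.sqrt(295.0 / bmi) * 100.0)  # keep weight < 300 kg
        weight = bmi * (h / 100.0) ** 2
        label = None
        if "label" in cohort.columns:
            label = "abnormal" if int(row["label"]) == 1 else "normal"
        records.append(
            PatientRecord(
                patient_id=f"{id_prefix}{i:05d}",
                age=float(row["age"]),
                sex=str(sexes[i]),
                height=round(h, 1),
                weight=round(weight, 1),
                respiration_rate=float(row["resp_rate"]),
                spo2=float(row["spo2"]),
                systolic_bp=float(row["systolic_bp"]),
                pulse_rate=float(row["heart_rate"]),
                temperature=float(row["temperature"]),
                blood_sugar=float(row["blood_sugar"]),
                label=label,
            )
        )
    return records


@dataclass
class AlertRecord:
    """One patient's fused alert, as written to the JSON alert report."""

    patient_id: str
    news2: News2Result
    alert: AlertResult
    timestamp: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "timestamp": self.timestamp,
            "news2_aggregate": self.news2.aggregate,
            "news2_clinical_risk": self.news2.clinical_risk.value,
            "classifier_abnormal": self.alert.classifier_abnormal,
            "news2_trigger": self.alert.news2_trigger,
            "hr_abnormal": self.alert.hr_abnormal,
            "alert_score": self.alert.alert_score,
            "level": self.alert.level.value,
            "alert_raised": self.alert.alert_raised,
        }


@dataclass
class PipelineResult:
    alerts: list[AlertRecord]
    rejects: list[RejectedRow]
    summary: dict[str, int]  # per-level counts


def run_pipeline(
    records: Sequence[PatientRecord],
    model: FittedModel,
    config: AlertConfig = DEFAULT_ALERT_CONFIG,
) -> PipelineResult:
    """Score, classify, flag and fuse a batch of records.

    Per-record scoring errors go into the rejects report without aborting
    the batch. Classifier predictions run as a single batch call, so the
    result is deterministic given the model and inputs.
    """
    scored: list[tuple[PatientRecord, News2Result]] = []
    rejects: list[RejectedRow] = []
    for i, record in enumerate(records):
        try:
            reasons = record.validation_errors()
            if reasons:
                raise ValueError("; ".join(reasons))
            scored.append((record, compute_news2(record.vitals())))
        except ValueError as exc:
            rejects.append(
                RejectedRow(row=i, patient_id=getattr(record, "patient_id", None), reason=str(exc))
            )
    summary = {level.value: 0 for level in AlertLevel}
    alerts: list[AlertRecord] = []
    if scored:
        features = records_to_features([r for r, _ in scored]).drop(
            columns=["label"], errors="ignore"
        )
        predictions = model.predict(features)
        for (record, news2), pred in zip(scored, predictions):
            alert = compute_alert(
                classifier_abnormal=bool(pred == 1),
                news2_aggregate=news2.aggregate,
                heart_rate=record.pulse_rate,
                config=config,
            )
            alerts.append(AlertRecord(patient_id=record.patient_id, news2=news2, alert=alert))
            summary[alert.level.value] += 1
    return PipelineResult(alerts=alerts, rejects=rejects, summary=summary)
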