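"""Per-medication adherence status flags and report/plot payloads.

Three checks combine into one clinician-facing flag per medication, with
strict precedence RED > YELLOW > GREEN > NONE:

* RED — current non-adherence: a refill gap longer than 30 days at any
  time in the record, or MPR < 0.8 at the latest observed day.  Both
  checks run on every medication regardless of drug class.
* YELLOW — predicted non-adherence: the drug-class logistic model
  forecasts poor adherence (1-year MPR < 0.8).  Predictions are only
  attempted for medications that passed the gap check, map to a
  configured class, and have at least 60 observed days.
* GREEN — adherent: either a full year is observed with MPR at day 365
  of at least 0.8 (observed outcome supersedes any forecast), or the
  model predicts acceptable adherence.
* NONE — no current problem and no basis for a forecast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date
from enum import Enum

from .adherence import (
    GAP_THRESHOLD_DAYS,
    MPR_THRESHOLD,
    GapInterval,
    build_possession_timeline,
    check_current_mpr,
    compute_mpr,
    detect_gaps,
    detect_gaps_cumulative,
    mpr_series,
)
from .prediction import (
    DrugClassMap,
    PredictionModel,
    PredictionResult,
    predict_one_year,
    select_prediction_day,
)
from .records import MedicationHistory, Patient


class Status(str, Enum):
    RED = "RED"
    YELLOW = "YELLOW"
    GREEN = "GREEN"
    NONE = "NONE"


class Reason(str, Enum):
    """Machine-readable evidence codes backing a status."""

    GAP_OVER_30 = "GAP_OVER_30"
    CURRENT_MPR_BELOW_0_8 = "CURRENT_MPR_BELOW_0_8"
    PREDICTED_POOR_1Y = "PREDICTED_POOR_1Y"
    PREDICTED_OK_1Y = "PREDICTED_OK_1Y"
    ACTUAL_1Y_OK = "ACTUAL_1Y_OK"
    NO_MODEL = "NO_MODEL"
    SPAN_TOO_SHORT = "SPAN_TOO_SHORT"


@dataclass(frozen=True)
class AssessmentOptions:
    """Thresholds and modes for classification; defaults are the
    conventional clinical values."""

    gap_threshold_days: int = GAP_THRESHOLD_DAYS
    mpr_threshold: float = MPR_THRESHOLD
    year_days: int = 365
    cap_at_one: bool = False
    gap_mode: str = "interval"  # or "cumulative"
    prediction_days: tuple[int, ...] = (60, 90, 120)

    def __post_init__(self):
        if self.gap_mode not in ("interval", "cumulative"):
            raise ValueError(f"gap_mode must be 'interval' or 'cumulative', got {self.gap_mode!r}")
        if self.gap_threshold_days <= 0 or self.mpr_threshold <= 0 or self.year_days <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class AdherenceAssessment:
    """One medication's status flag with its supporting evidence."""

    patient_id: str
    medication_id: str
    medication_name: str
    status: Status
    reasons: list[Reason]
    current_mpr: float | None
    first_fill_date: date
    last_fill_date: date
    drug_class: str | None
    gaps: list[GapInterval] = field(default_factory=list)
    prediction: PredictionResult | None = None

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "medication_id": self.medication_id,
            "medication_name": self.medication_name,
            "status": self.status.value,
            "reasons": [r.value for r in self.reasons],
            "current_mpr": self.current_mpr,
            "first_fill_date": self.first_fill_date.isoformat(),
            "last_fill_date": self.last_fill_date.isoformat(),
            "drug_class": self.drug_class,
            "gaps": [g.to_dict() for g in self.gaps],
            "prediction": self.prediction.to_dict() if self.prediction else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AdherenceAssessment":
        return cls(
            patient_id=d["patient_id"],
            medication_id=d["medication_id"],
            medication_name=d["medication_name"],
            status=Status(d["status"]),
            reasons=[Reason(r) for r in d["reasons"]],
            current_mpr=d["current_mpr"],
            first_fill_date=date.fromisoformat(d["first_fill_date"]),
            last_fill_date=date.fromisoformat(d["last_fill_date"]),
            drug_class=d.get("drug_class"),
            gaps=[GapInterval(**g) for g in d["gaps"]],
            prediction=(
                PredictionResult.from_dict(d["prediction"]) if d.get("prediction") else None
            ),
        )


def classify_medication(
    history: MedicationHistory,
    patient: Patient | None,
    class_map: DrugClassMap | None,
    models: dict[tuple[str, int], PredictionModel] | None,
    options: AssessmentOptions = AssessmentOptions(),
) -> AdherenceAssessment:
    """Run all three checks on one medication and resolve the status flag.

    Every history yields an assessment; missing configuration (no class
    map, no model, unknown age) degrades to NONE, never to an error.
    """
    drug_class = (
        class_map.lookup(history.medication_id, history.medication_name)
        if class_map
        else None
    )
    reasons: list[Reason] = []
    prediction: PredictionResult | None = None

    timeline = build_possession_timeline(history)
    if options.gap_mode == "cumulative":
        gaps = detect_gaps_cumulative(history, options.gap_threshold_days)
    else:
        gaps = detect_gaps(timeline, options.gap_threshold_days)

    horizon = history.horizon
    if horizon < 1:
        # observation window too short for any check
        return AdherenceAssessment(
            history.patient_id, history.medication_id, history.medication_name,
            Status.NONE, [Reason.SPAN_TOO_SHORT], None,
            history.first_fill_date, history.last_fill_date, drug_class,
            gaps=gaps,
        )

    if any(g.alert for g in gaps):
        reasons.append(Reason.GAP_OVER_30)
    flagged, current_mpr = check_current_mpr(
        history, options.mpr_threshold, options.cap_at_one
    )
    if flagged:
        reasons.append(Reason.CURRENT_MPR_BELOW_0_8)

    if reasons:
        status = Status.RED  # current non-adherence; no prediction is attempted
    elif horizon >= options.year_days and (
        compute_mpr(history, options.year_days, options.cap_at_one)
        >= options.mpr_threshold
    ):
        status = Status.GREEN
        reasons.append(Reason.ACTUAL_1Y_OK)
    else:
        day = select_prediction_day(horizon, options.prediction_days)
        model = (
            models.get((drug_class, day))
            if models and drug_class is not None and day is not None
            else None
        )
        age = patient.age_at_first_fill if patient else None
        if day is None:
            status = Status.NONE
            reasons.append(Reason.SPAN_TOO_SHORT)
        elif model is None or age is None:
            status = Status.NONE
            reasons.append(Reason.NO_MODEL)
        else:
            mpr_at_day = compute_mpr(history, day, cap_at_one=False)
            prediction = predict_one_year(age, mpr_at_day, model)
            if prediction.predicted_poor:
                status = Status.YELLOW
                reasons.append(Reason.PREDICTED_POOR_1Y)
            else:
                status = Status.GREEN
                reasons.append(Reason.PREDICTED_OK_1Y)

    return AdherenceAssessment(
        history.patient_id, history.medication_id, history.medication_name,
        status, reasons, current_mpr,
        history.first_fill_date, history.last_fill_date, drug_class,
        gaps=gaps, prediction=prediction,
    )


def assess_patient(
    histories: list[MedicationHistory],
    patient: Patient | None,
    class_map: DrugClassMap | None,
    models: dict[tuple[str, int], PredictionModel] | None,
    options: AssessmentOptions = AssessmentOptions(),
) -> list[AdherenceAssessment]:
    """Assess every medication of one patient.

    Ordering follows the clinician listing: medications in mapped drug
    classes first (classes alphabetical), then unmapped ones; each group
    alphabetical by medication name.
    """
    pid = {h.patient_id for h in histories}
    if len(pid) > 1:
        raise ValueError(f"histories span multiple patients: {sorted(pid)}")
    assessments = [
        classify_medication(h, patient, class_map, models, options) for h in histories
    ]
    assessments.sort(
        key=lambda a: (
            a.drug_class is None,
            a.drug_class or "",
            a.medication_name.lower(),
            a.medication_id,
        )
    )
    return assessments


def export_plot_data(
    history: MedicationHistory,
    assessment: AdherenceAssessment,
    options: AssessmentOptions = AssessmentOptions(),
) -> dict:
    """Plot payload for one medication: the running-MPR curve, fill-event
    markers, gap shading intervals, and the 0.8 threshold line.

    The payload mirrors the adherence computations exactly; a RED
    medication still exports its full series and gaps.
    """
    series = mpr_series(history, cap_at_one=options.cap_at_one)
    return {
        "patient_id": history.patient_id,
        "medication_id": history.medication_id,
        "medication_name": history.medication_name,
        "horizon_days": history.horizon,
        "mpr_series": [{"day": d, "mpr": v} for d, v in series.points],
        "fill_events": [
            {"day": d, "days_supply": s}
            for d, s in zip(history.fill_days, history.fill_supplies)
        ],
        "gap_regions": [g.to_dict() for g in assessment.gaps],
        "mpr_threshold": options.mpr_threshold,
        "status": assessment.status.value,
    }


def render_plot(payload: dict, path: str) -> None:
    """Render a plot payload to a static image (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3.5))
    days = [p["day"] for p in payload["mpr_series"]]
    vals = [p["mpr"] for p in payload["mpr_series"]]
    ax.plot(days, vals, color="#1f77b4", lw=2, label="running MPR")
    for g in payload["gap_regions"]:
        ax.axvspan(g["start_day"], g["end_day"], color="0.8", zorder=0)
    fill_days = [e["day"] for e in payload["fill_events"]]
    ax.plot(
        fill_days,
        [vals[days.index(d)] if d in days else 1.0 for d in fill_days],
        "o", color="#1f77b4", label="fills",
    )
    ax.axhline(payload["mpr_threshold"], color="red", ls="--", lw=1, label="0.8 threshold")
    ax.set_xlabel("days since first fill")
    ax.set_ylabel("MPR")
    ax.set_title(f"{payload['medication_name']} [{payload['status']}]")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


_STATUS_GLYPH = {
    "RED": "&#9888; RED",
    "YELLOW": "&#9888; YELLOW",
    "GREEN": "&#10003; GREEN",
    "NONE": "&mdash;",
}


def render_html_report(
    assessments: list[AdherenceAssessment],
    plot_payloads: list[dict] | None = None,
) -> str:
    """Static single-file HTML listing: name, first/last fill, status glyph,
    with per-medication plot payloads inlined as JSON."""
    rows = []
    for a in assessments:
        rows.append(
            "<tr class='{cls}'><td>{pid}</td><td>{name}</td><td>{first}</td>"
            "<td>{last}</td><td>{glyph}</td><td>{mpr}</td><td>{reasons}</td></tr>".format(
                cls=a.status.value.lower(),
                pid=a.patient_id,
                name=a.medication_name,
                first=a.first_fill_date.isoformat(),
                last=a.last_fill_date.isoformat(),
                glyph=_STATUS_GLYPH[a.status.value],
                mpr="" if a.current_mpr is None else f"{a.current_mpr:.3f}",
                reasons=", ".join(r.value for r in a.reasons),
            )
        )
    payload_json = json.dumps(plot_payloads or [], indent=1)
    return (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        "<title>Medication adherence report</title>\n<style>"
        "body{font-family:sans-serif} table{border-collapse:collapse}"
        "td,th{border:1px solid #999;padding:4px 8px}"
        "tr.red td{background:#fdd} tr.yellow td{background:#ffd}"
        "tr.green td{background:#dfd}"
        "</style></head><body>\n<h1>Medication adherence report</h1>\n"
        "<table><tr><th>Patient</th><th>Medication</th><th>First fill</th>"
        "<th>Last fill</th><th>Status</th><th>Current MPR</th><th>Evidence</th></tr>\n"
        + "\n".join(rows)
        + "\n</table>\n<script type='application/json' id='plot-data'>\n"
        + payload_json
        + "\n</script>\n</body></html>\n"
    )
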