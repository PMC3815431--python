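"""Status-flag semantics: RED (current non-adherence) > YELLOW (predicted)
> GREEN (observed or predicted adherent) > NONE (no basis)."""

import pytest

from mpr_monitor import (
    AssessmentOptions,
    DrugClassMap,
    Patient,
    PredictionModel,
    Status,
    assess_patient,
    classify_medication,
    export_plot_data,
)
from mpr_monitor.assessment import Reason, render_html_report
from mpr_monitor.adherence import build_possession_timeline, detect_gaps, mpr_series
from conftest import make_history

CLASS_MAP = DrugClassMap({"metformin": "c"})
POOR_MODELS = {
    ("c", d): PredictionModel("c", d, 10.0, 0.0, 0.0) for d in (60, 90, 120)
}
OK_MODELS = {
    ("c", d): PredictionModel("c", d, -10.0, 0.0, 0.0) for d in (60, 90, 120)
}
PATIENT = Patient("P1", 60.0)

# fill schedules realizing each check-outcome combination
GAP_ONLY = ([(0, 30), (70, 300)], 100)          # 40-day gap, MPR 3.3
MPR_ONLY = ([(0, 18), (25, 18), (50, 18), (75, 18)], 100)  # gaps of 7, MPR 0.72
GAP_AND_MPR = ([(0, 30)], 100)                  # 70-day gap, MPR 0.3
YEAR_OK = ([(d, 30) for d in range(0, 390, 30)], 365)      # MPR 1+ throughout
# MPR at day 365 below 0.8 but clean and back at 0.8 by the horizon
YEAR_LOW = ([(d, 20) for d in range(0, 390, 30)] + [(390, 300)], 700)
SHORT_CLEAN = ([(0, 30), (30, 30), (60, 30)], 90)          # clean, 90-day span
TOO_SHORT = ([(0, 30), (30, 30)], 59)                      # clean, span < 60


def classify(fills_horizon, models=None, class_map=CLASS_MAP, patient=PATIENT,
             options=AssessmentOptions()):
    fills, horizon = fills_horizon
    h = make_history(fills, horizon, medication_id="metformin",
                     medication_name="Metformin")
    return classify_medication(h, patient, class_map, models, options)


class TestStatusTruthTable:
    """Exhaustive combinations of {gap alert} x {low current MPR} x
    {prediction poor/ok/unavailable} x {year observed ok/low/absent}."""

    @pytest.mark.parametrize("models", [None, POOR_MODELS, OK_MODELS])
    @pytest.mark.parametrize(
        "scenario, expected_reasons",
        [
            (GAP_ONLY, {Reason.GAP_OVER_30}),
            (MPR_ONLY, {Reason.CURRENT_MPR_BELOW_0_8}),
            (GAP_AND_MPR, {Reason.GAP_OVER_30, Reason.CURRENT_MPR_BELOW_0_8}),
        ],
    )
    def test_current_non_adherence_is_red_regardless_of_model(
        self, scenario, expected_reasons, models
    ):
        a = classify(scenario, models)
        assert a.status is Status.RED
        assert set(a.reasons) == expected_reasons
        assert a.prediction is None  # RED medications never carry predictions

    @pytest.mark.parametrize("models", [None, POOR_MODELS, OK_MODELS])
    def test_observed_adherent_year_is_green_and_supersedes_forecast(self, models):
        a = classify(YEAR_OK, models)
        assert a.status is Status.GREEN
        assert a.reasons == [Reason.ACTUAL_1Y_OK]
        assert a.prediction is None

    @pytest.mark.parametrize("scenario", [YEAR_LOW, SHORT_CLEAN])
    def test_clean_with_poor_forecast_is_yellow(self, scenario):
        a = classify(scenario, POOR_MODELS)
        assert a.status is Status.YELLOW
        assert a.reasons == [Reason.PREDICTED_POOR_1Y]
        assert a.prediction is not None and a.prediction.predicted_poor

    @pytest.mark.parametrize("scenario", [YEAR_LOW, SHORT_CLEAN])
    def test_clean_with_acceptable_forecast_is_green(self, scenario):
        a = classify(scenario, OK_MODELS)
        assert a.status is Status.GREEN
        assert a.reasons == [Reason.PREDICTED_OK_1Y]
        assert not a.prediction.predicted_poor

    @pytest.mark.parametrize("scenario", [YEAR_LOW, SHORT_CLEAN])
    def test_clean_without_forecast_basis_is_none(self, scenario):
        assert classify(scenario, None).status is Status.NONE
        assert classify(scenario, POOR_MODELS, class_map=DrugClassMap()).status is Status.NONE
        unaged = classify(scenario, POOR_MODELS, patient=Patient("P1", None))
        assert unaged.status is Status.NONE
        assert Reason.NO_MODEL in unaged.reasons

    def test_clean_span_under_60_days_is_none(self):
        a = classify(TOO_SHORT, POOR_MODELS)
        assert a.status is Status.NONE
        assert a.reasons == [Reason.SPAN_TOO_SHORT]

    def test_long_trailing_gap_example(self):
        # a 196-day trailing gap is current non-adherence for any drug class
        h = make_history([(0, 30)], horizon=226, medication_id="cyclobenzaprine",
                         medication_name="Cyclobenzaprine")
        a = classify_medication(h, PATIENT, CLASS_MAP, POOR_MODELS)
        assert a.status is Status.RED
        (gap,) = a.gaps
        assert gap.length == 196


class TestClassificationDetails:
    def test_prediction_uses_latest_available_day(self):
        a = classify(YEAR_LOW, POOR_MODELS)
        assert a.prediction.prediction_day == 120

    def test_prediction_feeds_uncapped_mpr_at_selected_day(self):
        fills, horizon = SHORT_CLEAN
        h = make_history(fills, horizon, medication_id="metformin")
        a = classify_medication(h, PATIENT, CLASS_MAP, POOR_MODELS)
        from mpr_monitor import compute_mpr

        assert a.prediction.mpr_at_prediction_day == compute_mpr(h, 90)

    def test_rerun_is_deterministic(self):
        first = classify(YEAR_LOW, POOR_MODELS)
        second = classify(YEAR_LOW, POOR_MODELS)
        assert first == second

    def test_cumulative_gap_mode_changes_gap_semantics_only(self):
        # interior 40-day lapse recovered by the end: interval mode alerts,
        # cumulative mode sees no net shortfall; MPR is unaffected
        fills, horizon = GAP_ONLY
        interval = classify(GAP_ONLY, None)
        cumulative = classify(GAP_ONLY, None,
                              options=AssessmentOptions(gap_mode="cumulative"))
        assert interval.status is Status.RED
        assert cumulative.status is not Status.RED
        assert interval.current_mpr == cumulative.current_mpr

    def test_every_history_yields_an_assessment(self):
        histories = [
            make_history(fills, horizon, medication_id=f"m{i}",
                         medication_name=f"Drug{i}")
            for i, (fills, horizon) in enumerate(
                [GAP_ONLY, MPR_ONLY, YEAR_OK, TOO_SHORT]
            )
        ]
        out = assess_patient(histories, PATIENT, CLASS_MAP, POOR_MODELS)
        assert len(out) == len(histories)


class TestPatientOrdering:
    def test_mapped_classes_first_then_alphabetical(self):
        cmap = DrugClassMap({
            "ramipril": "antihypertensives",
            "metformin": "oral_hypoglycemics",
        })
        names = ["Zaleplon", "Ramipril", "Metformin", "Aspirin"]
        histories = [
            make_history([(0, 30)], 40, medication_id=n.lower(), medication_name=n)
            for n in names
        ]
        out = assess_patient(histories, PATIENT, cmap, None)
        assert [a.medication_name for a in out] == [
            "Ramipril",   # antihypertensives
            "Metformin",  # oral_hypoglycemics
            "Aspirin",    # unmapped, alphabetical
            "Zaleplon",
        ]

    def test_empty_patient_gives_empty_list(self):
        assert assess_patient([], PATIENT, CLASS_MAP, None) == []

    def test_mixed_patients_rejected(self):
        histories = [
            make_history([(0, 30)], 40, patient_id=p) for p in ("P1", "P2")
        ]
        with pytest.raises(ValueError, match="multiple patients"):
            assess_patient(histories, PATIENT, None, None)


class TestPlotExport:
    def test_payload_mirrors_adherence_outputs(self):
        fills, horizon = GAP_ONLY
        h = make_history(fills, horizon, medication_id="metformin")
        a = classify_medication(h, PATIENT, CLASS_MAP, None)
        payload = export_plot_data(h, a)
        series = mpr_series(h)
        assert payload["mpr_series"] == [
            {"day": d, "mpr": v} for d, v in series.points
        ]
        assert [e["day"] for e in payload["fill_events"]] == h.fill_days
        gaps = detect_gaps(build_possession_timeline(h))
        assert payload["gap_regions"] == [g.to_dict() for g in gaps]
        assert payload["mpr_threshold"] == 0.8

    def test_perfect_coverage_payload_is_flat_with_no_gaps(self):
        h = make_history([(0, 30), (30, 30)], 60, medication_id="metformin")
        a = classify_medication(h, PATIENT, None, None)
        payload = export_plot_data(h, a)
        assert payload["gap_regions"] == []
        assert all(p["mpr"] >= 1.0 for p in payload["mpr_series"])
        capped = export_plot_data(
            h, a, AssessmentOptions(cap_at_one=True)
        )
        assert {p["mpr"] for p in capped["mpr_series"]} == {1.0}

    def test_html_report_lists_every_medication(self):
        histories = [
            make_history([(0, 30)], 100, medication_id=f"m{i}",
                         medication_name=f"Drug{i}")
            for i in range(3)
        ]
        assessments = assess_patient(histories, PATIENT, None, None)
        html = render_html_report(assessments)
        for a in assessments:
            assert a.medication_name in html
        assert html.count("<tr class=") == 3
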