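"""Logistic one-year non-adherence prediction from early fill behavior.

A two-covariate logistic model — patient age at first fill (years) and
the running MPR at the prediction day — forecasts poor adherence (MPR
below 0.8 one year after the first fill).  Models are fit per drug
class and per prediction day (60, 90 or 120 days after the first fill)
and supplied as external configuration; this module only applies them.

    P(poor) = 1 / (1 + exp(-(intercept + beta_age * age + beta_mpr * mpr)))

The packaged ``data/example_models.json`` carries synthetic placeholder
coefficients for the three chronic-medication classes (antihyperlipidemics,
antihypertensives, oral hypoglycemics); substitute coefficients estimated
from real claims data for clinical use.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import TextIO

PREDICTION_DAYS = (60, 90, 120)
DEFAULT_CLASSIFICATION_THRESHOLD = 0.5


class ConfigError(ValueError):
    """A configuration file (drug-class map or model coefficients) is invalid."""


class DrugClassMap:
    """Case-insensitive lookup from medication code or name to drug class.

    Unmapped medications are legal: no prediction is made for classes
    without configured models (e.g. muscle relaxants).
    """

    def __init__(self, entries: dict[str, str] | None = None):
        self._entries: dict[str, str] = {}
        for key, cls in (entries or {}).items():
            self.add(key, cls)

    def add(self, key: str, drug_class: str) -> None:
        norm = key.strip().lower()
        existing = self._entries.get(norm)
        if existing is not None and existing != drug_class:
            raise ConfigError(
                f"duplicate key {key!r} maps to both {existing!r} and {drug_class!r}"
            )
        self._entries[norm] = drug_class

    def lookup(self, medication_id: str, medication_name: str | None = None) -> str | None:
        """Class for a medication, trying the code then the display name."""
        cls = self._entries.get(medication_id.strip().lower())
        if cls is None and medication_name:
            cls = self._entries.get(medication_name.strip().lower())
        return cls

    def __len__(self) -> int:
        return len(self._entries)

    def classes(self) -> set[str]:
        return set(self._entries.values())


@dataclass(frozen=True)
class PredictionModel:
    """Logistic coefficients for one (drug class, prediction day) pair.

    The outcome is poor adherence, defined as 1-year MPR < 0.8; the
    binary call uses ``classification_threshold`` (default 0.5) on the
    predicted probability.
    """

    drug_class: str
    prediction_day: int
    intercept: float
    beta_age: float
    beta_mpr: float
    classification_threshold: float = DEFAULT_CLASSIFICATION_THRESHOLD

    def __post_init__(self):
        if self.prediction_day not in PREDICTION_DAYS:
            raise ConfigError(
                f"prediction_day must be one of {PREDICTION_DAYS}, got {self.prediction_day}"
            )
        if not (0 < self.classification_threshold < 1):
            raise ConfigError("classification_threshold must be in (0, 1)")


@dataclass(frozen=True)
class PredictionResult:
    """Outcome of applying one model to one medication."""

    drug_class: str
    prediction_day: int
    mpr_at_prediction_day: float
    probability_poor: float
    predicted_poor: bool

    def to_dict(self) -> dict:
        return {
            "drug_class": self.drug_class,
            "prediction_day": self.prediction_day,
            "mpr_at_prediction_day": self.mpr_at_prediction_day,
            "probability_poor": self.probability_poor,
            "predicted_poor": self.predicted_poor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PredictionResult":
        return cls(
            drug_class=d["drug_class"],
            prediction_day=int(d["prediction_day"]),
            mpr_at_prediction_day=float(d["mpr_at_prediction_day"]),
            probability_poor=float(d["probability_poor"]),
            predicted_poor=bool(d["predicted_poor"]),
        )


def load_drug_class_map(source: TextIO | str) -> DrugClassMap:
    """Load a two-column TSV ``key<TAB>drug_class``; ``#`` starts a comment.

    A key appearing twice with conflicting classes is a fatal ambiguity.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    cmap = DrugClassMap()
    for n, raw in enumerate(source, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = [p.strip() for p in line.split("\t") if p.strip()]
        if len(parts) != 2:
            raise ConfigError(f"line {n}: expected 'key<TAB>drug_class', got {raw!r}")
        cmap.add(parts[0], parts[1])
    return cmap


def load_model_config(source: TextIO | str) -> dict[tuple[str, int], PredictionModel]:
    """Load model coefficients from a JSON array of records.

    Each record requires ``drug_class``, ``prediction_day`` (60/90/120),
    ``intercept``, ``beta_age`` and ``beta_mpr``; ``classification_threshold``
    is optional.  At most one model per (class, day).
    """
    text = source if isinstance(source, str) else source.read()
    try:
        records = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ConfigError(f"model config is not valid JSON: {exc}") from exc
    if not isinstance(records, list):
        raise ConfigError("model config must be a JSON array of objects")
    models: dict[tuple[str, int], PredictionModel] = {}
    required = ("drug_class", "prediction_day", "intercept", "beta_age", "beta_mpr")
    for i, rec in enumerate(records):
        missing = [k for k in required if k not in rec]
        if missing:
            raise ConfigError(f"model record {i}: missing field(s) {', '.join(missing)}")
        model = PredictionModel(
            drug_class=str(rec["drug_class"]),
            prediction_day=int(rec["prediction_day"]),
            intercept=float(rec["intercept"]),
            beta_age=float(rec["beta_age"]),
            beta_mpr=float(rec["beta_mpr"]),
            classification_threshold=float(
                rec.get("classification_threshold", DEFAULT_CLASSIFICATION_THRESHOLD)
            ),
        )
        key = (model.drug_class, model.prediction_day)
        if key in models:
            raise ConfigError(f"duplicate model for {key}")
        models[key] = model
    return models


def load_example_models() -> dict[tuple[str, int], PredictionModel]:
    """Packaged synthetic placeholder coefficients (not estimated from data)."""
    text = resources.files("mpr_monitor").joinpath("data/example_models.json").read_text()
    return load_model_config(text)


def load_example_drug_classes() -> DrugClassMap:
    """Packaged example drug-class map covering a handful of common agents."""
    text = resources.files("mpr_monitor").joinpath("data/example_classes.tsv").read_text()
    return load_drug_class_map(text)


def select_prediction_day(
    observation_span_days: int, available_days: tuple[int, ...] = PREDICTION_DAYS
) -> int | None:
    """Latest available prediction day not after the observed span.

    None when the span is shorter than the earliest prediction day — no
    forecast is possible before 60 days of observation.
    """
    if observation_span_days < 0:
        raise ValueError("observation span must be >= 0")
    eligible = [d for d in available_days if d <= observation_span_days]
    return max(eligible) if eligible else None


def predict_one_year(
    age: float, mpr_at_day: float, model: PredictionModel
) -> PredictionResult:
    """Apply one logistic model; probability is of POOR 1-year adherence."""
    if mpr_at_day < 0:
        raise ValueError("MPR must be nonnegative")
    eta = model.intercept + model.beta_age * age + model.beta_mpr * mpr_at_day
    # overflow-safe logistic
    if eta >= 0:
        probability = 1.0 / (1.0 + math.exp(-eta))
    else:
        e = math.exp(eta)
        probability = e / (1.0 + e)
    return PredictionResult(
        drug_class=model.drug_class,
        prediction_day=model.prediction_day,
        mpr_at_prediction_day=mpr_at_day,
        probability_poor=probability,
        predicted_poor=probability >= model.classification_threshold,
    )
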