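"""Model-construction audit: topic ratings and occurrence-data exclusion gates.

A pre-existing habitat model is audited against a fixed rubric of 23 topics in
five categories (occurrence data, environmental covariates, modelling
algorithm, extent/resolution, model selection & thresholds).  Each topic gets
one of three ratings — ``ideal``, ``acceptable``, or ``caution`` ("interpret
with caution").  Three of the occurrence-data topics are computed directly
from the occurrence records and carry hard *exclusion gates*; a model must
pass all three gates to be "acceptable" for probable-habitat mapping:

* number of occurrences — gate fails below 10 records;
* age of occurrences — gate fails when the majority of records are from
  1950 or earlier;
* spatial accuracy — gate fails when the majority of records carry imprecise
  accuracy classes (6-10).

The remaining 20 topics require judgement about contractor reports and are
supplied as an evidence config (topic key -> rating + note); topics with no
evidence default to ``caution``, since an undocumented modelling step is not
defensible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ConfigError, ParameterError
from .occurrences import (
    CLASS3_MAX_RADIUS_M,
    PRECISE_CLASSES,
    OccurrenceRecord,
    _radius_within,
)

__all__ = [
    "RATINGS",
    "TOPICS",
    "COMPUTED_TOPICS",
    "QUALITATIVE_TOPICS",
    "TopicRating",
    "RubricEvaluation",
    "rate_occurrence_count",
    "rate_occurrence_age",
    "rate_occurrence_accuracy",
    "evaluate_model",
    "write_report_csv",
    "write_report_markdown",
]

RATINGS = ("ideal", "acceptable", "caution")

#: (category, topic) pairs; the full fixed rubric.
TOPICS: tuple[tuple[str, str], ...] = (
    # occurrence data used to develop the model
    ("occurrence_data", "number_of_occurrences"),
    ("occurrence_data", "age_of_occurrences"),
    ("occurrence_data", "spatial_accuracy"),
    ("occurrence_data", "occurrence_status"),
    ("occurrence_data", "species_identification"),
    ("occurrence_data", "spatial_bias"),
    ("occurrence_data", "spatial_distribution"),
    ("occurrence_data", "absence_data"),
    # environmental covariates
    ("covariates", "ecological_relevance"),
    ("covariates", "comprehensiveness"),
    ("covariates", "resolution_and_scale"),
    ("covariates", "covariate_accuracy"),
    ("covariates", "number_of_covariates"),
    ("covariates", "covariate_currency"),
    ("covariates", "covariate_selection"),
    ("covariates", "covariate_correlation"),
    # modelling algorithm
    ("algorithm", "use_in_literature"),
    ("algorithm", "interactions"),
    ("algorithm", "nonlinearity"),
    # modelling extent and resolution
    ("extent_resolution", "model_extent"),
    ("extent_resolution", "output_resolution"),
    # model selection and thresholds
    ("selection_thresholds", "model_selection"),
    ("selection_thresholds", "threshold_selection"),
)

COMPUTED_TOPICS = ("number_of_occurrences", "age_of_occurrences", "spatial_accuracy")
QUALITATIVE_TOPICS = tuple(t for _, t in TOPICS if t not in COMPUTED_TOPICS)
_CATEGORY = {t: c for c, t in TOPICS}


@dataclass(frozen=True)
class TopicRating:
    category: str
    topic: str
    rating: str
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.topic not in _CATEGORY:
            raise ConfigError(f"unknown rubric topic: {self.topic!r}")
        if self.rating not in RATINGS:
            raise ConfigError(f"rating must be one of {RATINGS}, got {self.rating!r}")


@dataclass(frozen=True)
class RubricEvaluation:
    """Full audit of one model: every topic rated, gates decided."""

    model_id: str
    ratings: tuple[TopicRating, ...]
    gate_count_pass: bool
    gate_age_pass: bool
    gate_accuracy_pass: bool

    @property
    def acceptable(self) -> bool:
        """Eligible for probable-habitat mapping: all three gates passed."""
        return self.gate_count_pass and self.gate_age_pass and self.gate_accuracy_pass

    def rating_for(self, topic: str) -> TopicRating:
        for r in self.ratings:
            if r.topic == topic:
                return r
        raise KeyError(topic)


# ---------------------------------------------------------------------------
# the three computed occurrence-data topics


def rate_occurrence_count(n: int, small_range_flag: bool = False) -> tuple[str, bool]:
    """Rating and gate for the number of occurrences used to build a model.

    Gate fails below 10.  More than 50 is ideal, 25-50 acceptable, fewer than
    25 caution — unless the species is flagged as having a very small,
    well-understood range, in which case a small count is still acceptable.
    """
    if n < 0:
        raise ParameterError(f"occurrence count must be >= 0, got {n}")
    gate_pass = n >= 10
    if n > 50:
        rating = "ideal"
    elif n >= 25:
        rating = "acceptable"
    else:
        rating = "acceptable" if small_range_flag else "caution"
    return rating, gate_pass


def rate_occurrence_age(years: Sequence[int]) -> tuple[str, bool]:
    """Rating and gate for record ages.

    Gate fails when the majority (> 50%) of records are from 1950 or earlier.
    All records from 2000 on is ideal; more than 20% from 1980 or earlier is
    caution; otherwise acceptable (i.e., >= 80% of records are 1981-present).
    """
    years = list(years)
    if not years:
        raise ParameterError("years must be non-empty")
    n = len(years)
    frac_pre1951 = sum(y <= 1950 for y in years) / n
    gate_pass = frac_pre1951 <= 0.5
    if all(y >= 2000 for y in years):
        rating = "ideal"
    elif sum(y <= 1980 for y in years) / n > 0.20:
        rating = "caution"
    else:
        rating = "acceptable"
    return rating, gate_pass


def rate_occurrence_accuracy(
    classes: Sequence[int],
    class3_radii_m: Sequence[float | None] | None = None,
) -> tuple[str, bool]:
    """Rating and gate for locational accuracy.

    A record is precise iff its class is 1, 2 or 4, or it is class 3 with
    equivalent radius <= 150 m (``class3_radii_m`` parallel to ``classes``;
    only class-3 entries are consulted).  Gate fails when the majority of
    records have classes 6-10.  All precise is ideal, >= 80% precise
    acceptable, otherwise caution.
    """
    classes = list(classes)
    if not classes:
        raise ParameterError("classes must be non-empty")
    if any(not 1 <= c <= 10 for c in classes):
        raise ParameterError("accuracy classes must be in [1, 10]")
    if class3_radii_m is None:
        class3_radii_m = [None] * len(classes)
    n = len(classes)

    def precise(c: int, r: float | None) -> bool:
        if c in PRECISE_CLASSES:
            return True
        return c == 3 and r is not None and _radius_within(r, CLASS3_MAX_RADIUS_M)

    frac_imprecise_class = sum(6 <= c <= 10 for c in classes) / n
    gate_pass = frac_imprecise_class <= 0.5
    frac_precise = sum(precise(c, r) for c, r in zip(classes, class3_radii_m)) / n
    if frac_precise == 1.0:
        rating = "ideal"
    elif frac_precise >= 0.80:
        rating = "acceptable"
    else:
        rating = "caution"
    return rating, gate_pass


# ---------------------------------------------------------------------------


def evaluate_model(
    model_id: str,
    records: Iterable[OccurrenceRecord],
    evidence: Mapping[str, str | Mapping[str, str]] | None = None,
    small_range_flag: bool = False,
) -> RubricEvaluation:
    """Audit one model against the full rubric.

    ``records`` are the occurrence records for the model-building window
    (pre-thinning: the gates judge the data the model was built from).
    ``evidence`` maps qualitative topic keys to a rating (``"caution"`` /
    ``"acceptable"`` / ``"ideal"``) or ``{"rating": ..., "note": ...}``;
    absent topics default to ``caution``.
    """
    records = list(records)
    evidence = dict(evidence or {})
    for key in evidence:
        if key not in QUALITATIVE_TOPICS:
            hint = " (computed from records, not configurable)" if key in COMPUTED_TOPICS else ""
            raise ConfigError(f"unknown rubric topic in evidence config: {key!r}{hint}")

    n = len(records)
    count_rating, gate_count = rate_occurrence_count(n, small_range_flag)
    if n:
        age_rating, gate_age = rate_occurrence_age([r.year for r in records])
        acc_rating, gate_acc = rate_occurrence_accuracy(
            [r.accuracy_class for r in records],
            [r.equivalent_radius_m if r.accuracy_class == 3 else None for r in records],
        )
    else:
        age_rating = acc_rating = "caution"
        gate_age = gate_acc = False

    computed = {
        "number_of_occurrences": (count_rating, f"{n} occurrences in window"),
        "age_of_occurrences": (age_rating, f"computed from {n} record years"),
        "spatial_accuracy": (acc_rating, f"computed from {n} accuracy classes"),
    }
    ratings = []
    for category, topic in TOPICS:
        if topic in computed:
            rating, note = computed[topic]
        else:
            entry = evidence.get(topic)
            if entry is None:
                rating, note = "caution", "no details provided"
            elif isinstance(entry, str):
                rating, note = entry, ""
            else:
                rating, note = entry.get("rating", "caution"), entry.get("note", "")
        ratings.append(TopicRating(category, topic, rating, note))

    return RubricEvaluation(
        model_id=model_id,
        ratings=tuple(ratings),
        gate_count_pass=gate_count,
        gate_age_pass=gate_age,
        gate_accuracy_pass=gate_acc,
    )


def write_report_csv(evaluations: Sequence[RubricEvaluation], path: str | Path) -> None:
    """Topic-by-model rating table, one row per (model, topic)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["model_id", "category", "topic", "rating", "evidence", "acceptable"])
        for ev in evaluations:
            for r in ev.ratings:
                writer.writerow(
                    [ev.model_id, r.category, r.topic, r.rating, r.evidence, ev.acceptable]
                )


def write_report_markdown(evaluations: Sequence[RubricEvaluation], path: str | Path) -> None:
    """Side-by-side Markdown table: one row per topic, one column per model."""
    lines = ["| Category | Topic | " + " | ".join(ev.model_id for ev in evaluations) + " |"]
    lines.append("|" + "---|" * (2 + len(evaluations)))
    for category, topic in TOPICS:
        cells = []
        for ev in evaluations:
            r = ev.rating_for(topic)
            cells.append(f"{r.rating}" + (f" — {r.evidence}" if r.evidence else ""))
        lines.append(f"| {category} | {topic} | " + " | ".join(cells) + " |")
    gates = " | ".join("acceptable" if ev.acceptable else "excluded" for ev in evaluations)
    lines.append(f"| — | overall | {gates} |")
    Path(path).write_text("\n".join(lines) + "\n")
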