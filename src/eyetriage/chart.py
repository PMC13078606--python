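"""Urgency grading, service routing and the chart-based disposition algorithm.

The disposition chart mirrors the paper-and-laminate symptom acuity charts
used in emergency eye clinics: each row pairs a symptom-feature pattern with
an urgency grade (A-D) and the eye-care service best placed to deliver care
at that urgency.  A compiled symptom report is matched against every row and
the most urgent matching row wins; red-flag (fast-tracked) reports bypass the
chart entirely and are sent to the emergency department the same day.
"""

from __future__ import annotations

import enum
import functools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "UrgencyGrade",
    "UrgencyBand",
    "ServiceRoute",
    "Disposition",
    "ChartRule",
    "AcuityChart",
    "OutcomeRecord",
    "dispose",
    "urgency_band",
    "ess_suitable",
    "community_care_suitable",
    "load_chart",
    "reference_chart",
]


@functools.total_ordering
class UrgencyGrade(enum.Enum):
    """Four-level urgency grade: A (same day) through D (within the week).

    Comparison follows *urgency*: ``UrgencyGrade.A > UrgencyGrade.D``.
    ``code`` gives the 1..4 integer coding used by the ordinal agreement
    statistics (A=1 ... D=4, equally spaced).
    """

    A = "A"
    B = "B"
    C = "C"
    D = "D"

    @property
    def code(self) -> int:
        return "ABCD".index(self.value) + 1

    def __lt__(self, other: "UrgencyGrade") -> bool:
        if not isinstance(other, UrgencyGrade):
            return NotImplemented
        return self.code > other.code  # higher code = lower urgency

    @classmethod
    def from_string(cls, s: str) -> "UrgencyGrade":
        try:
            return cls(s.strip().upper())
        except ValueError:
            raise ValueError(f"unknown urgency grade {s!r}; expected one of A, B, C, D") from None


class UrgencyBand(enum.Enum):
    URGENT = "urgent"          # same day (A) or within 24 h (B)
    SEMIURGENT = "semiurgent"  # within 48-72 h (C)
    LOWER = "lower"            # within the week (D)


_BANDS: Mapping[UrgencyGrade, UrgencyBand] = {
    UrgencyGrade.A: UrgencyBand.URGENT,
    UrgencyGrade.B: UrgencyBand.URGENT,
    UrgencyGrade.C: UrgencyBand.SEMIURGENT,
    UrgencyGrade.D: UrgencyBand.LOWER,
}


def urgency_band(grade: UrgencyGrade) -> UrgencyBand:
    """Map a grade to its clinical band (urgent = {A, B})."""
    if not isinstance(grade, UrgencyGrade):
        raise TypeError(f"expected UrgencyGrade, got {grade!r}")
    return _BANDS[grade]


class ServiceRoute(enum.Enum):
    """Eye-care service a patient is directed to.

    Ordered from most to least specialist; the community/optometry/pharmacy
    routes are deliverable through commissioned community enhanced service
    schemes (ESSs).
    """

    ED = "ED"
    EEC = "EEC"
    HOSPITAL_URGENT_EYE_SERVICE = "hospital_urgent_eye_service"
    COMMUNITY_URGENT_EYE_SERVICE = "community_urgent_eye_service"
    PRIVATE_OPTOMETRY = "private_optometry"
    PHARMACY = "pharmacy"

    @property
    def ess_eligible(self) -> bool:
        return self in _ESS_ROUTES

    @property
    def specialism_rank(self) -> int:
        """0 = most specialist (ED); used to break urgency ties."""
        return _SERVICE_ORDER.index(self)


_SERVICE_ORDER = [
    ServiceRoute.ED,
    ServiceRoute.EEC,
    ServiceRoute.HOSPITAL_URGENT_EYE_SERVICE,
    ServiceRoute.COMMUNITY_URGENT_EYE_SERVICE,
    ServiceRoute.PRIVATE_OPTOMETRY,
    ServiceRoute.PHARMACY,
]
_ESS_ROUTES = frozenset(
    {
        ServiceRoute.COMMUNITY_URGENT_EYE_SERVICE,
        ServiceRoute.PRIVATE_OPTOMETRY,
        ServiceRoute.PHARMACY,
    }
)


@dataclass(frozen=True)
class Disposition:
    """Suggested urgency + service route for a triaged patient."""

    urgency: UrgencyGrade
    service: ServiceRoute
    fast_track: bool = False

    def __post_init__(self) -> None:
        if self.fast_track and (self.urgency is not UrgencyGrade.A or self.service is not ServiceRoute.ED):
            raise ValueError("fast-track dispositions must be grade A routed to ED")

    def to_dict(self) -> dict:
        return {
            "urgency": self.urgency.value,
            "service": self.service.value,
            "fast_track": self.fast_track,
        }


@dataclass(frozen=True)
class ChartRule:
    """One chart row: fire when every feature in ``features`` is present."""

    features: frozenset
    urgency: UrgencyGrade
    service: ServiceRoute
    label: str = ""

    def matches(self, report_features: Iterable[str]) -> bool:
        return self.features <= set(report_features)


@dataclass
class AcuityChart:
    """Ordered rule list plus a default disposition for unmatched reports."""

    rules: Sequence[ChartRule]
    default: Disposition = field(
        default_factory=lambda: Disposition(
            UrgencyGrade.C, ServiceRoute.COMMUNITY_URGENT_EYE_SERVICE
        )
    )

    def feature_vocabulary(self) -> frozenset:
        vocab: set = set()
        for rule in self.rules:
            vocab |= rule.features
        return frozenset(vocab)

    def validate_vocabulary(self, questionnaire_tags: Iterable[str]) -> list:
        """Chart features not emitted by the companion questionnaire."""
        tags = set(questionnaire_tags)
        return sorted(self.feature_vocabulary() - tags)


@dataclass(frozen=True)
class OutcomeRecord:
    """What the clinic actually did at the subsequent appointment.

    A patient whose visit needed none of these is, for the evaluation,
    suitable for community care.
    """

    imaging: bool = False
    other_diagnostic_tests: bool = False
    prescription_medication: bool = False
    surgical_procedure: bool = False


def dispose(report, chart: AcuityChart) -> Disposition:
    """Map a compiled symptom report to a disposition via the chart.

    Every matching row contributes; the most urgent grade among matches wins
    and, on an urgency tie, the more specialist service.  Fast-tracked
    reports short-circuit to (A, ED) regardless of chart content.
    """
    if report.fast_tracked:
        return Disposition(UrgencyGrade.A, ServiceRoute.ED, fast_track=True)

    matched = [rule for rule in chart.rules if rule.matches(report.features)]
    if not matched:
        return chart.default
    best = max(matched, key=lambda r: (r.urgency, -r.service.specialism_rank))
    return Disposition(best.urgency, best.service, fast_track=False)


def ess_suitable(disposition: Disposition) -> bool:
    """True when the routed service is deliverable via a community ESS."""
    return disposition.service.ess_eligible


def community_care_suitable(outcome: OutcomeRecord) -> bool:
    """True iff the visit required no imaging, tests, prescription or surgery."""
    return not (
        outcome.imaging
        or outcome.other_diagnostic_tests
        or outcome.prescription_medication
        or outcome.surgical_procedure
    )


# ---------------------------------------------------------------------------
# Config I/O

def _rule_from_dict(d: Mapping) -> ChartRule:
    return ChartRule(
        features=frozenset(d["features"]),
        urgency=UrgencyGrade.from_string(d["urgency"]),
        service=ServiceRoute(d["service"]),
        label=d.get("label", ""),
    )


def load_chart(source) -> AcuityChart:
    """Load an acuity chart from a JSON file path, file object or dict."""
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    elif hasattr(source, "read"):
        doc = json.load(source)
    else:
        doc = source
    if "rules" not in doc:
        raise ValueError("chart config must contain a 'rules' array")
    rules = [_rule_from_dict(r) for r in doc["rules"]]
    default_doc = doc.get("default", {"urgency": "C", "service": "community_urgent_eye_service"})
    default = Disposition(
        UrgencyGrade.from_string(default_doc["urgency"]),
        ServiceRoute(default_doc["service"]),
    )
    return AcuityChart(rules=rules, default=default)


def chart_to_dict(chart: AcuityChart) -> dict:
    return {
        "rules": [
            {
                "features": sorted(r.features),
                "urgency": r.urgency.value,
                "service": r.service.value,
                "label": r.label,
            }
            for r in chart.rules
        ],
        "default": {
            "urgency": chart.default.urgency.value,
            "service": chart.default.service.value,
        },
    }


def reference_chart() -> AcuityChart:
    """The chart shipped with the package (see ``data/reference_chart.json``)."""
    path = Path(__file__).parent / "data" / "reference_chart.json"
    return load_chart(path)
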