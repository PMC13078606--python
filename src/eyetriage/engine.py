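"""Branching-logic symptom questionnaire engine.

A questionnaire is a DAG of multiple-choice questions: each chosen answer
names the next question (or a terminal marker) and emits zero or more
symptom-feature tags.  Red-flag answers (recent sight-threatening injury,
recent sudden loss of vision, stroke symptoms) are *fast-track* options: the
session ends immediately and the compiled report is flagged so the
disposition layer can force same-day emergency-department routing.

Sessions are forward-only (no backtracking), bounded by a hard question
budget, and fully deterministic: a recorded response trace replays to the
identical symptom report.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Mapping, Optional, Sequence

TERMINAL = "END"
DEFAULT_MAX_QUESTIONS = 25

__all__ = [
    "TERMINAL",
    "DEFAULT_MAX_QUESTIONS",
    "PresentingConcern",
    "QuestionCategory",
    "AnswerOption",
    "Question",
    "QuestionnaireGraph",
    "ResponseTrace",
    "SymptomReport",
    "Eligibility",
    "InvalidAnswerError",
    "InconsistentTraceError",
    "validate_graph",
    "run_session",
    "compile_report",
    "enumerate_paths",
    "check_eligibility",
    "load_questionnaire",
    "reference_questionnaire",
]


class PresentingConcern(enum.Enum):
    """The four top-level complaints offered by the initial filter question."""

    RED_OR_PAINFUL_EYE = "red_or_painful_eye"
    PAINLESS_VISUAL_DISTURBANCE = "painless_visual_disturbance"
    EYE_INJURY = "eye_injury"
    EYELID_PROBLEM = "eyelid_problem"


class QuestionCategory(enum.Enum):
    SYMPTOMATOLOGY = "symptomatology"
    OPHTHALMIC_HISTORY = "ophthalmic_history"
    MEDICATION = "medication"


class InvalidAnswerError(ValueError):
    """The answer provider returned an option not offered by the question."""


class InconsistentTraceError(ValueError):
    """A response trace does not follow the questionnaire's edges."""


@dataclass(frozen=True)
class AnswerOption:
    id: str
    label: str
    next: str = TERMINAL
    fast_track: bool = False
    feature_tags: frozenset = frozenset()
    concern: Optional[PresentingConcern] = None  # set on entry-question options

    @property
    def is_terminal(self) -> bool:
        return self.next == TERMINAL


@dataclass(frozen=True)
class Question:
    id: str
    text: str
    options: Sequence[AnswerOption]
    category: QuestionCategory = QuestionCategory.SYMPTOMATOLOGY
    allows_free_text: bool = False

    def option(self, option_id: str) -> AnswerOption:
        for opt in self.options:
            if opt.id == option_id:
                return opt
        raise InvalidAnswerError(
            f"question {self.id!r} has no option {option_id!r} "
            f"(offered: {[o.id for o in self.options]})"
        )


@dataclass
class QuestionnaireGraph:
    questions: Mapping[str, Question]
    entry: str
    max_questions: int = DEFAULT_MAX_QUESTIONS

    def feature_vocabulary(self) -> frozenset:
        tags: set = set()
        for q in self.questions.values():
            for opt in q.options:
                tags |= opt.feature_tags
        return frozenset(tags)


@dataclass
class ResponseTrace:
    """Ordered (question_id, option_id) pairs plus session metadata."""

    answers: list = field(default_factory=list)
    free_text: Optional[str] = None
    duration_seconds: float = 0.0
    likert: Optional[int] = None

    def __post_init__(self) -> None:
        if self.likert is not None and self.likert not in range(1, 6):
            raise ValueError(f"likert score must be in 1..5, got {self.likert}")
        if self.duration_seconds < 0:
            raise ValueError("duration_seconds must be nonnegative")


@dataclass(frozen=True)
class SymptomReport:
    presenting_concern: PresentingConcern
    features: frozenset
    fast_tracked: bool = False
    free_text: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "presenting_concern": self.presenting_concern.value,
            "features": sorted(self.features),
            "fast_tracked": self.fast_tracked,
            "free_text": self.free_text,
        }


# ---------------------------------------------------------------------------
# Eligibility gates (applied before a session starts, not questionnaire nodes)

@dataclass(frozen=True)
class Eligibility:
    eligible: bool
    reason: Optional[str] = None


MIN_AGE_YEARS = 13
MAX_SYMPTOM_AGE_DAYS = 7


def check_eligibility(age_years: float, symptom_onset_days: float) -> Eligibility:
    """Age >= 13 and recent-onset (within one week) symptoms only."""
    if age_years < MIN_AGE_YEARS:
        return Eligibility(False, f"patient must be at least {MIN_AGE_YEARS} years old")
    if symptom_onset_days > MAX_SYMPTOM_AGE_DAYS:
        return Eligibility(False, "symptoms must have started within the last week")
    return Eligibility(True)


# ---------------------------------------------------------------------------
# Validation

def validate_graph(graph: QuestionnaireGraph) -> list:
    """Structural audit of a questionnaire; returns a list of violations.

    An empty list means the graph satisfies every invariant: the entry node
    exists, all edges resolve, the graph is acyclic, each non-terminal
    question offers at least two options, option ids are unique per question,
    entry options declare a presenting concern, fast-track options terminate,
    and no root-to-terminal path exceeds the question budget.
    """
    violations: list = []

    if graph.max_questions < 1:
        violations.append("graph: max_questions must be positive")
    if graph.entry not in graph.questions:
        violations.append(f"graph: entry question {graph.entry!r} not defined")
        return violations

    for qid, q in graph.questions.items():
        if q.id != qid:
            violations.append(f"{qid}: key does not match question id {q.id!r}")
        ids = [o.id for o in q.options]
        if len(ids) != len(set(ids)):
            violations.append(f"{qid}: duplicate option ids")
        if len(q.options) < 2:
            violations.append(f"{qid}: fewer than 2 options")
        for opt in q.options:
            if opt.fast_track and not opt.is_terminal:
                violations.append(f"{qid}/{opt.id}: fast_track option must be terminal")
            if not opt.is_terminal and opt.next not in graph.questions:
                violations.append(f"{qid}/{opt.id}: next question {opt.next!r} not defined")

    entry_q = graph.questions[graph.entry]
    for opt in entry_q.options:
        if opt.concern is None:
            violations.append(f"{graph.entry}/{opt.id}: entry option must declare a presenting concern")

    # Cycle detection + longest path by iterative DFS over resolvable edges.
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {qid: WHITE for qid in graph.questions}
    longest: dict = {}
    cyclic = False

    def edges(qid: str) -> Iterator[str]:
        for opt in graph.questions[qid].options:
            if not opt.is_terminal and opt.next in graph.questions:
                yield opt.next

    def visit(start: str) -> None:
        nonlocal cyclic
        stack = [(start, iter(edges(start)))]
        color[start] = GRAY
        while stack:
            qid, it = stack[-1]
            advanced = False
            for nxt in it:
                if color[nxt] == GRAY:
                    cyclic = True
                elif color[nxt] == WHITE:
                    color[nxt] = GRAY
                    stack.append((nxt, iter(edges(nxt))))
                    advanced = True
                    break
            if not advanced:
                color[qid] = BLACK
                longest[qid] = 1 + max(
                    (longest.get(nxt, 0) for nxt in edges(qid)), default=0
                )
                stack.pop()

    visit(graph.entry)
    if cyclic:
        violations.append("graph: acyclic invariant violated (cycle reachable from entry)")
    elif longest.get(graph.entry, 0) > graph.max_questions:
        violations.append(
            f"graph: max_questions exceeded (longest path "
            f"{longest[graph.entry]} > limit {graph.max_questions})"
        )

    unreachable = [qid for qid, c in color.items() if c == WHITE]
    for qid in sorted(unreachable):
        violations.append(f"{qid}: unreachable from entry")

    return violations


# ---------------------------------------------------------------------------
# Session execution

def run_session(
    graph: QuestionnaireGraph,
    answer_provider: Callable[[Question], str],
    free_text: Optional[str] = None,
    likert: Optional[int] = None,
    duration_seconds: float = 0.0,
):
    """Run one interactive session; returns ``(ResponseTrace, SymptomReport)``.

    ``answer_provider`` is called with each question in turn and must return
    the id of one of its options.  The session stops at the first terminal
    or fast-track option, or when the question budget is exhausted.
    """
    trace = ResponseTrace(free_text=free_text, likert=likert, duration_seconds=duration_seconds)
    qid = graph.entry
    for _ in range(graph.max_questions):
        question = graph.questions[qid]
        option = question.option(answer_provider(question))
        trace.answers.append((question.id, option.id))
        if option.fast_track or option.is_terminal:
            break
        qid = option.next
    else:
        raise RuntimeError(
            f"session exceeded max_questions={graph.max_questions}; graph not validated?"
        )
    return trace, compile_report(graph, trace)


def compile_report(graph: QuestionnaireGraph, trace: ResponseTrace) -> SymptomReport:
    """Replay a trace into a symptom report (pure function of the trace)."""
    if not trace.answers:
        raise InconsistentTraceError("trace is empty; the entry question must be answered")
    if len(trace.answers) > graph.max_questions:
        raise InconsistentTraceError("trace longer than the question budget")

    expected = graph.entry
    features: set = set()
    fast_tracked = False
    concern: Optional[PresentingConcern] = None

    for i, (qid, oid) in enumerate(trace.answers):
        if qid != expected:
            raise InconsistentTraceError(
                f"trace step {i}: expected question {expected!r}, got {qid!r}"
            )
        question = graph.questions.get(qid)
        if question is None:
            raise InconsistentTraceError(f"trace step {i}: unknown question {qid!r}")
        try:
            option = question.option(oid)
        except InvalidAnswerError as exc:
            raise InconsistentTraceError(str(exc)) from None
        features |= option.feature_tags
        if qid == graph.entry:
            concern = option.concern
        if option.fast_track:
            fast_tracked = True
        if option.fast_track or option.is_terminal:
            if i != len(trace.answers) - 1:
                raise InconsistentTraceError(f"trace continues past terminal at step {i}")
            expected = TERMINAL
        else:
            expected = option.next

    if concern is None:
        raise InconsistentTraceError("entry answer does not determine a presenting concern")
    return SymptomReport(
        presenting_concern=concern,
        features=frozenset(features),
        fast_tracked=fast_tracked,
        free_text=trace.free_text,
    )


def enumerate_paths(graph: QuestionnaireGraph) -> Iterator[ResponseTrace]:
    """Yield every root-to-terminal answer path as a replayable trace.

    Exhaustive over the option tree; intended for auditing shipped configs
    (the reference questionnaire has a few hundred paths).
    """
    stack = [(graph.entry, [])]
    while stack:
        qid, answers = stack.pop()
        question = graph.questions[qid]
        for option in reversed(question.options):
            step = answers + [(qid, option.id)]
            if option.fast_track or option.is_terminal:
                yield ResponseTrace(answers=step)
            else:
                stack.append((option.next, step))


# ---------------------------------------------------------------------------
# Config I/O

def _question_from_dict(d: Mapping) -> Question:
    options = []
    for od in d["options"]:
        options.append(
            AnswerOption(
                id=od["id"],
                label=od.get("label", od["id"]),
                next=od.get("next", TERMINAL),
                fast_track=bool(od.get("fast_track", False)),
                feature_tags=frozenset(od.get("feature_tags", [])),
                concern=PresentingConcern(od["concern"]) if "concern" in od else None,
            )
        )
    return Question(
        id=d["id"],
        text=d["text"],
        options=options,
        category=QuestionCategory(d.get("category", "symptomatology")),
        allows_free_text=bool(d.get("allows_free_text", False)),
    )


def load_questionnaire(source, validate: bool = True) -> QuestionnaireGraph:
    """Load a questionnaire from a JSON path, file object or dict.

    With ``validate=True`` (default) a structurally invalid graph raises
    ``ValueError`` listing every violation.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    elif hasattr(source, "read"):
        doc = json.load(source)
    else:
        doc = source

    for key in ("entry", "questions"):
        if key not in doc:
            raise ValueError(f"questionnaire config missing required key {key!r}")
    questions = {qd["id"]: _question_from_dict(qd) for qd in doc["questions"]}
    graph = QuestionnaireGraph(
        questions=questions,
        entry=doc["entry"],
        max_questions=int(doc.get("max_questions", DEFAULT_MAX_QUESTIONS)),
    )
    if validate:
        violations = validate_graph(graph)
        if violations:
            raise ValueError("invalid questionnaire: " + "; ".join(violations))
    return graph


def reference_questionnaire() -> QuestionnaireGraph:
    """The demonstrative questionnaire shipped with the package.

    The entry question reproduces the four-way presenting-concern filter;
    the branches are a stand-in authored to exercise every row of the
    shipped reference chart (the deployed tool's question set is
    proprietary and unpublished).
    """
    path = Path(__file__).parent / "data" / "reference_questionnaire.json"
    return load_questionnaire(path)
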