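"""Cohort CSV I/O, run manifests, and evaluation-report rendering.

Cohort dialect: comma-separated UTF-8 with a required header
``patient_id,nurse_grade,tool_grade,oph1_grade,oph2_grade,concern,imaging,
tests,prescription,procedure,likert,duration_s``; grades as letters A-D,
booleans as 0/1, empty fields = missing.  Extra columns (for example a
``tool_service`` route column) round-trip unchanged.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .simulate import COHORT_COLUMNS, CONCERNS, GRADE_LETTERS

__all__ = [
    "CohortReadError",
    "RowError",
    "read_cohort",
    "write_cohort",
    "RunManifest",
    "render_report_text",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = "1.0"

_GRADE_COLS = ["nurse_grade", "tool_grade", "oph1_grade", "oph2_grade"]
_FLAG_COLS = ["imaging", "tests", "prescription", "procedure"]


@dataclass(frozen=True)
class RowError:
    line: int  # 1-based line number in the file (header = line 1)
    message: str


class CohortReadError(ValueError):
    """Raised for fatal cohort-file problems (missing file/columns)."""


def read_cohort(path, strict: bool = True):
    """Read a cohort CSV; returns ``(DataFrame, list[RowError])``.

    Malformed rows (unknown grade letter, Likert outside 1-5, non-0/1
    outcome flag, duplicate patient id) are collected with their line
    numbers and dropped from the returned table.  With ``strict=True`` any
    row error raises :class:`CohortReadError` instead.  A missing required
    column is always fatal.
    """
    path = Path(path)
    if not path.exists():
        raise CohortReadError(f"cohort file not found: {path}")
    df = pd.read_csv(path, dtype={"patient_id": str}, keep_default_na=True)

    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortReadError(f"cohort file missing required columns: {missing}")

    errors: List[RowError] = []
    bad = np.zeros(len(df), dtype=bool)

    def flag(mask: np.ndarray, message: str) -> None:
        for idx in np.nonzero(mask)[0]:
            errors.append(RowError(line=int(idx) + 2, message=message.format(row=df.iloc[idx])))
        nonlocal bad
        bad |= mask

    dupes = df["patient_id"].duplicated(keep="first").to_numpy()
    flag(dupes, "duplicate patient_id {row[patient_id]!r}")

    for col in _GRADE_COLS:
        vals = df[col].astype(str).str.strip().str.upper()
        present = df[col].notna() & (vals != "")
        invalid = (present & ~vals.isin(GRADE_LETTERS)).to_numpy()
        flag(invalid, f"invalid grade in {col}: {{row[{col}]!r}}")
        df[col] = vals.where(present & vals.isin(GRADE_LETTERS))

    present = df["concern"].notna() & (df["concern"].astype(str).str.strip() != "")
    invalid = (present & ~df["concern"].isin(CONCERNS)).to_numpy()
    flag(invalid, "unknown presenting concern {row[concern]!r}")

    likert = pd.to_numeric(df["likert"], errors="coerce")
    invalid = (df["likert"].notna() & (likert.isna() | ~likert.isin([1, 2, 3, 4, 5]))).to_numpy()
    flag(invalid, "likert score outside 1..5: {row[likert]!r}")
    df["likert"] = likert

    for col in _FLAG_COLS:
        numeric = pd.to_numeric(df[col], errors="coerce")
        invalid = (df[col].notna() & ~numeric.isin([0, 1])).to_numpy()
        flag(invalid, f"{col} flag must be 0 or 1, got {{row[{col}]!r}}")
        df[col] = numeric

    df["duration_s"] = pd.to_numeric(df["duration_s"], errors="coerce")

    if errors and strict:
        detail = "; ".join(f"line {e.line}: {e.message}" for e in errors[:10])
        raise CohortReadError(f"{len(errors)} malformed row(s): {detail}")
    return df.loc[~bad].reset_index(drop=True), errors


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort table in the canonical dialect (empty = missing)."""
    out = df.copy()
    for col in _FLAG_COLS:
        if col in out.columns:
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    if "likert" in out.columns:
        out["likert"] = out["likert"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run manifests

def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written alongside every CLI output."""

    command: str
    inputs: dict = field(default_factory=dict)   # path -> sha256
    seed: Optional[int] = None
    timestamp: str = ""
    version: str = __version__

    @classmethod
    def create(cls, command: str, input_paths=(), seed: Optional[int] = None) -> "RunManifest":
        return cls(
            command=command,
            inputs={str(p): _sha256(p) for p in input_paths if Path(p).exists()},
            seed=seed,
            timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Report rendering

def _pct(x: Optional[float]) -> str:
    return "--" if x is None else f"{100 * x:.1f}"


def _ci_pct(ci) -> str:
    return "--" if not ci else f"({100 * ci[0]:.1f}-{100 * ci[1]:.1f})"


def render_report_text(report: dict) -> str:
    """Human-readable evaluation summary mirroring the accuracy/agreement tables."""
    lines = []
    lines.append("Triage evaluation report")
    lines.append("=" * 60)
    lines.append(f"Cohort rows: {report.get('n_rows', 0)}")
    ref = report.get("reference")
    if ref:
        lines.append(
            f"Reference standard: {ref['n_urgent']}/{ref['n']} urgent "
            f"({_pct(ref['n_urgent'] / ref['n'] if ref['n'] else None)}%)"
        )

    acc = report.get("accuracy") or {}
    if acc:
        lines.append("")
        lines.append("Accuracy for identifying urgent cases (vs reference standard)")
        lines.append(f"{'rater':<8}{'sens % (95% CI)':<26}{'spec % (95% CI)':<26}")
        for rater, a in acc.items():
            lines.append(
                f"{rater:<8}"
                f"{_pct(a['sensitivity']) + ' ' + _ci_pct(a['ci_sens']):<26}"
                f"{_pct(a['specificity']) + ' ' + _ci_pct(a['ci_spec']):<26}"
            )
        pa = report.get("percent_agreement_urgent") or {}
        if pa:
            lines.append(
                "Percent agreement (urgent dichotomy): "
                + ", ".join(f"{r} {_pct(v)}%" for r, v in pa.items())
            )
    else:
        lines.append("")
        lines.append("Accuracy: no pairs available")

    agr = report.get("agreement") or {}
    lines.append("")
    lines.append("Interrater agreement, urgency grades A-D (quadratically weighted kappa)")
    if agr:
        lines.append(f"{'raters':<18}{'kappa (95% CI)':<24}{'band':<16}{'agr urgent %':<12}")
        for pair, a in agr.items():
            if "error" in a:
                lines.append(f"{pair:<18}undefined: {a['error']}")
                continue
            ci = a["ci"]
            kappa_str = f"{a['kappa']:.2f} ({ci[0]:.2f} to {ci[1]:.2f})"
            lines.append(
                f"{pair:<18}{kappa_str:<24}{a['band']:<16}"
                f"{_pct(a.get('percent_agreement')):<12}"
            )
    else:
        lines.append("no pairs available")

    down = report.get("downrate_vs_nurse")
    if down:
        lines.append("")
        lines.append("Down-rating of urgent nurse dispositions")
        for who, d in down.items():
            lines.append(f"  {who}: {d['n_downrated']} downrated ({_pct(d['proportion'])}%)")

    ou = report.get("over_under_vs_reference")
    if ou:
        lines.append("")
        lines.append("Over/under-estimation vs combined reviewer grade")
        for rater, d in ou.items():
            lines.append(f"  {rater}: over {_pct(d['over'])}%, under {_pct(d['under'])}%")

    for key, label in (
        ("ess_suitable", "Suggested suitable for community ESS"),
        ("community_care_suitable", "Suitable for community care by outcome"),
    ):
        d = report.get(key)
        if d:
            lines.append(f"{label}: {d['n']} ({_pct(d['proportion'])}%)")

    lik = report.get("likert")
    if lik:
        sd = f"{lik['sd']:.2f}" if lik["sd"] is not None else "--"
        lines.append(
            f"Likert acceptability: mean {lik['mean']:.2f} (SD {sd}; n={lik['n']}), "
            f"top-2 {_pct(lik['prop_top2'])}%"
        )
    dur = report.get("duration_minutes")
    if dur:
        lines.append(
            f"Test duration: mean {dur['mean']:.1f} min (SD {dur['sd']:.1f}; "
            f"range {dur['min']:.1f}-{dur['max']:.1f}; n={dur['n']})"
        )
    return "\n".join(lines) + "\n"


def write_report(report: dict, json_path, text_path=None) -> None:
    doc = {"schema_version": REPORT_SCHEMA_VERSION, "report": report}
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if text_path is not None:
        with open(text_path, "w", encoding="utf-8") as fh:
            fh.write(render_report_text(report))
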