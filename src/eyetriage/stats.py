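"""Diagnostic-accuracy and interrater-agreement evaluation.

Implements the evaluation used to validate a triage tool against nurse
triage with ophthalmologist review as the reference standard:

* reference-standard construction — two independent ophthalmologist urgency
  grades combined by taking the more urgent on disagreement; a case is
  reference-urgent when at least one reviewer graded it A or B;
* 2x2 accuracy — sensitivity/specificity with exact (Clopper-Pearson)
  binomial confidence intervals, and the McNemar test with continuity
  correction for paired comparisons;
* ordinal agreement — quadratically weighted Cohen kappa with an asymptotic
  (large-sample) confidence interval and the conventional interpretation
  bands, plus percent agreement on the urgent dichotomy;
* service-redistribution analyses — down-rating of urgent dispositions and
  over/under-estimation relative to the reference grades.

Grade vectors may be sequences of :class:`~eyetriage.chart.UrgencyGrade`,
single letters ``"A".."D"``, or integer codes 1..4 (A=1 ... D=4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .chart import OutcomeRecord, UrgencyBand, UrgencyGrade, urgency_band

__all__ = [
    "Confusion2x2",
    "CrossTabKxK",
    "AccuracyResult",
    "AgreementResult",
    "combine_reference",
    "reference_urgent",
    "grades_to_codes",
    "is_urgent",
    "crosstab",
    "confusion",
    "clopper_pearson",
    "accuracy",
    "percent_agreement_urgent",
    "weighted_kappa",
    "kappa_band",
    "mcnemar_cc",
    "downrate_analysis",
    "over_under_estimation",
    "likert_summary",
]

N_GRADES = 4


# ---------------------------------------------------------------------------
# Grade handling

def _to_code(g) -> int:
    if isinstance(g, UrgencyGrade):
        return g.code
    if isinstance(g, str):
        return UrgencyGrade.from_string(g).code
    code = int(g)
    if not 1 <= code <= N_GRADES:
        raise ValueError(f"grade code {g!r} outside 1..{N_GRADES}")
    return code


def grades_to_codes(grades: Sequence) -> np.ndarray:
    """Normalise a grade vector to integer codes A=1 ... D=4."""
    return np.array([_to_code(g) for g in grades], dtype=np.int64)


def is_urgent(grades: Sequence) -> np.ndarray:
    """Boolean vector: grade in the urgent band (A or B)."""
    return grades_to_codes(grades) <= 2


def combine_reference(g1, g2) -> UrgencyGrade:
    """Combine two reviewer grades, taking the more urgent on disagreement."""
    code = min(_to_code(g1), _to_code(g2))
    return UrgencyGrade("ABCD"[code - 1])


def reference_urgent(oph1, oph2) -> bool:
    """Reference-standard dichotomy: urgent iff at least one reviewer graded A/B.

    Equivalent to the combined (more-urgent-wins) grade falling in the
    urgent band.
    """
    if oph1 is None or oph2 is None:
        raise ValueError("both reviewer grades are required for the reference standard")
    return urgency_band(combine_reference(oph1, oph2)) is UrgencyBand.URGENT


# ---------------------------------------------------------------------------
# 2x2 accuracy

@dataclass(frozen=True)
class Confusion2x2:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn


def confusion(pred_urgent: Sequence[bool], ref_urgent_v: Sequence[bool]) -> Confusion2x2:
    """Tally a prediction/reference boolean pair into a 2x2 table."""
    pred = np.asarray(pred_urgent, dtype=bool)
    ref = np.asarray(ref_urgent_v, dtype=bool)
    if pred.shape != ref.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {ref.shape}")
    return Confusion2x2(
        tp=int(np.sum(pred & ref)),
        fp=int(np.sum(pred & ~ref)),
        fn=int(np.sum(~pred & ref)),
        tn=int(np.sum(~pred & ~ref)),
    )


def clopper_pearson(x: int, n: int, alpha: float = 0.05) -> Tuple[float, float]:
    """Exact binomial confidence interval from beta-distribution quantiles."""
    if not 0 <= x <= n or n == 0:
        raise ValueError(f"need 0 <= x <= n with n > 0, got x={x}, n={n}")
    lower = 0.0 if x == 0 else float(sps.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(sps.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lower, upper


@dataclass(frozen=True)
class AccuracyResult:
    sensitivity: float
    specificity: float
    ci_sens: Tuple[float, float]
    ci_spec: Tuple[float, float]
    n_positive: int
    n_negative: int
    method: str = "clopper-pearson"

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ci_sens": list(self.ci_sens),
            "ci_spec": list(self.ci_spec),
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "method": self.method,
        }


def accuracy(c: Confusion2x2, alpha: float = 0.05) -> AccuracyResult:
    """Sensitivity and specificity with exact 95% (default) intervals."""
    if c.n_positive == 0 or c.n_negative == 0:
        raise ValueError(
            "accuracy undefined: empty margin "
            f"(positives={c.n_positive}, negatives={c.n_negative})"
        )
    return AccuracyResult(
        sensitivity=c.tp / c.n_positive,
        specificity=c.tn / c.n_negative,
        ci_sens=clopper_pearson(c.tp, c.n_positive, alpha),
        ci_spec=clopper_pearson(c.tn, c.n_negative, alpha),
        n_positive=c.n_positive,
        n_negative=c.n_negative,
    )


def percent_agreement_urgent(pred_grades: Sequence, ref_urgent_v: Sequence[bool]) -> float:
    """Raw agreement with the reference on the urgent/non-urgent dichotomy."""
    ref = np.asarray(ref_urgent_v, dtype=bool)
    if ref.size == 0:
        raise ValueError("empty cohort")
    c = confusion(is_urgent(pred_grades), ref)
    return (c.tp + c.tn) / c.n


def mcnemar_cc(b: int, c: int) -> Tuple[float, float]:
    """McNemar test with continuity correction on discordant-pair counts.

    ``b`` and ``c`` are the two off-diagonal counts of the paired 2x2 table.
    Returns ``(statistic, p_value)`` with statistic (|b-c|-1)^2/(b+c) and the
    p-value from the upper tail of chi-square with 1 df.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be nonnegative")
    if b + c == 0:
        raise ValueError("McNemar test undefined: no discordant pairs")
    statistic = (abs(b - c) - 1) ** 2 / (b + c)
    return statistic, float(sps.chi2.sf(statistic, df=1))


# ---------------------------------------------------------------------------
# Ordinal agreement

@dataclass(frozen=True)
class CrossTabKxK:
    counts: np.ndarray  # rater1 rows, rater2 columns

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("cross-tabulation must be a square matrix")
        if counts.shape[0] < 2:
            raise ValueError("need at least 2 categories")
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts.astype(np.float64))

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def crosstab(grades1: Sequence, grades2: Sequence, k: int = N_GRADES) -> CrossTabKxK:
    """K x K cross-tabulation of two aligned grade vectors."""
    c1 = grades_to_codes(grades1)
    c2 = grades_to_codes(grades2)
    if c1.shape != c2.shape:
        raise ValueError("grade vectors must be aligned")
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (c1 - 1, c2 - 1), 1)
    return CrossTabKxK(counts)


@dataclass(frozen=True)
class AgreementResult:
    kappa: float
    ci: Tuple[float, float]
    se: float
    weights: str
    percent_agreement: Optional[float]
    band: str
    n: int

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "ci": list(self.ci),
            "se": self.se,
            "weights": self.weights,
            "percent_agreement": self.percent_agreement,
            "band": self.band,
            "n": self.n,
        }


def _agreement_weights(k: int, weights: str) -> np.ndarray:
    i = np.arange(k)[:, None]
    j = np.arange(k)[None, :]
    if weights == "quadratic":
        return 1.0 - ((i - j) ** 2) / (k - 1) ** 2
    if weights == "linear":
        return 1.0 - np.abs(i - j) / (k - 1)
    if weights == "unweighted":
        return (i == j).astype(float)
    raise ValueError(f"unknown weight scheme {weights!r}")


def weighted_kappa(
    tab: CrossTabKxK,
    weights: str = "quadratic",
    alpha: float = 0.05,
    percent_agreement: Optional[float] = None,
    ci_method: str = "asymptotic",
    bootstrap_reps: int = 2000,
    rng: Optional[np.random.Generator] = None,
) -> AgreementResult:
    """Weighted Cohen kappa with confidence interval and interpretation band.

    Quadratic disagreement weights ((i-j)/(k-1))^2 penalise large ordinal
    discrepancies disproportionately, reflecting that a two-band triage miss
    carries more clinical risk than a one-band miss.  The default confidence
    interval uses the large-sample variance of weighted kappa; a seeded
    multinomial bootstrap is available via ``ci_method="bootstrap"``.
    """
    counts = tab.counts
    n = tab.total
    if n <= 0:
        raise ValueError("empty cross-tabulation")
    k = tab.k
    w = _agreement_weights(k, weights)

    p = counts / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    expected = np.outer(row, col)

    po_w = float((w * p).sum())
    pe_w = float((w * expected).sum())
    if math.isclose(pe_w, 1.0, abs_tol=1e-12):
        raise ValueError(
            "degenerate marginal: expected weighted agreement is 1 "
            "(each rater effectively uses a single category); kappa undefined"
        )
    kappa = (po_w - pe_w) / (1.0 - pe_w)

    if ci_method == "asymptotic":
        # Large-sample variance of weighted kappa (Fleiss, Cohen & Everitt).
        wbar_row = w @ col        # \bar{w}_{i.}
        wbar_col = row @ w        # \bar{w}_{.j}
        term = w * (1 - pe_w) - (wbar_row[:, None] + wbar_col[None, :]) * (1 - po_w)
        var = (float((p * term**2).sum()) - (po_w * pe_w - 2 * pe_w + po_w) ** 2) / (
            n * (1 - pe_w) ** 4
        )
        se = math.sqrt(max(var, 0.0))
        z = sps.norm.ppf(1 - alpha / 2)
        ci = (max(kappa - z * se, -1.0), min(kappa + z * se, 1.0))
    elif ci_method == "bootstrap":
        if rng is None:
            rng = np.random.default_rng(0)
        flat = counts.ravel()
        reps = np.empty(bootstrap_reps)
        for r in range(bootstrap_reps):
            resampled = rng.multinomial(int(n), flat / n).reshape(k, k)
            reps[r] = _kappa_point(resampled, w)
        se = float(np.std(reps, ddof=1))
        lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
        ci = (float(lo), float(hi))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    return AgreementResult(
        kappa=kappa,
        ci=ci,
        se=se,
        weights=weights,
        percent_agreement=percent_agreement,
        band=kappa_band(kappa),
        n=int(n),
    )


def _kappa_point(counts: np.ndarray, w: np.ndarray) -> float:
    n = counts.sum()
    p = counts / n
    expected = np.outer(p.sum(axis=1), p.sum(axis=0))
    po = (w * p).sum()
    pe = (w * expected).sum()
    if math.isclose(pe, 1.0, abs_tol=1e-12):
        return 1.0
    return (po - pe) / (1 - pe)


_KAPPA_BANDS = [
    (0.00, "no agreement"),
    (0.20, "none to slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
]


def kappa_band(kappa: float) -> str:
    """Conventional interpretation label for a kappa value.

    The published cut-offs are closed two-decimal intervals (0.21-0.40 fair,
    etc.); values are rounded to 2 dp before banding so e.g. 0.204 -> 0.20
    ("none to slight") and 0.205 -> 0.21 ("fair").
    """
    if not -1.0 - 1e-9 <= kappa <= 1.0 + 1e-9:
        raise ValueError(f"kappa {kappa} outside [-1, 1]")
    rounded = round(kappa, 2)
    for upper, label in _KAPPA_BANDS:
        if rounded <= upper:
            return label
    return "almost perfect"


# ---------------------------------------------------------------------------
# Redistribution analyses

def downrate_analysis(comparator_grades: Sequence, against_grades: Sequence) -> Tuple[int, float]:
    """Down-rating of urgent dispositions by a second rater.

    Restricted to rows the ``against`` rater graded urgent (A/B); counts how
    many of those the comparator graded C or D.  Returns ``(count,
    proportion-of-against-urgent)``.
    """
    comp = grades_to_codes(comparator_grades)
    against = grades_to_codes(against_grades)
    if comp.shape != against.shape:
        raise ValueError("grade vectors must be aligned")
    urgent_mask = against <= 2
    n_urgent = int(urgent_mask.sum())
    if n_urgent == 0:
        raise ValueError("no urgent rows in the against-rater grades")
    n_down = int(np.sum(comp[urgent_mask] >= 3))
    return n_down, n_down / n_urgent


def over_under_estimation(grades: Sequence, reference_grades: Sequence) -> Tuple[float, float]:
    """Fractions of cases graded strictly more / less urgent than the reference."""
    g = grades_to_codes(grades)
    ref = grades_to_codes(reference_grades)
    if g.shape != ref.shape:
        raise ValueError("grade vectors must be aligned")
    if g.size == 0:
        raise ValueError("empty cohort")
    over = float(np.mean(g < ref))   # lower code = more urgent
    under = float(np.mean(g > ref))
    return over, under


# ---------------------------------------------------------------------------
# Descriptive summaries

def likert_summary(values: Sequence) -> Tuple[float, Optional[float], int, float]:
    """Mean, sample SD, n and top-2 (scores 4-5) fraction of Likert ratings.

    Missing values (None/NaN) are dropped; SD is ``None`` for a single
    observation (sample SD with n-1 denominator is undefined).
    """
    clean = np.array(
        [v for v in values if v is not None and not (isinstance(v, float) and math.isnan(v))],
        dtype=np.float64,
    )
    if clean.size == 0:
        raise ValueError("no non-missing Likert values")
    if np.any((clean < 1) | (clean > 5)):
        raise ValueError("Likert values must lie in 1..5")
    mean = float(clean.mean())
    sd = float(clean.std(ddof=1)) if clean.size > 1 else None
    prop_top2 = float(np.mean(clean >= 4))
    return mean, sd, int(clean.size), prop_top2


def community_care_suitability(outcomes: Sequence[OutcomeRecord]) -> Tuple[int, float]:
    """Count and fraction of visits needing no tests, medication or surgery."""
    from .chart import community_care_suitable

    flags = [community_care_suitable(o) for o in outcomes]
    if not flags:
        raise ValueError("empty outcome list")
    n_suitable = int(sum(flags))
    return n_suitable, n_suitable / len(flags)


# ---------------------------------------------------------------------------
# Cohort-level evaluation

_RATER_COLS = {
    "nurse": "nurse_grade",
    "tool": "tool_grade",
    "oph1": "oph1_grade",
    "oph2": "oph2_grade",
}

_KAPPA_PAIRS = [
    ("oph1", "oph2"),
    ("oph1", "nurse"),
    ("oph1", "tool"),
    ("oph2", "nurse"),
    ("oph2", "tool"),
    ("tool", "nurse"),
]


def evaluate_cohort(df, kappa_ci_method: str = "asymptotic", bootstrap_reps: int = 2000, seed: int = 0) -> dict:
    """Run the full evaluation over a cohort table.

    ``df`` is a pandas DataFrame in the cohort CSV dialect (grade letters in
    ``nurse_grade``/``tool_grade``/``oph1_grade``/``oph2_grade``, outcome
    flags 0/1, empty = missing).  Rows missing a grade are excluded
    listwise from each statistic that needs that rater; exclusion counts are
    reported.  Returns a nested plain-dict report (JSON-serialisable).
    """
    rng = np.random.default_rng(seed)
    report: dict = {"n_rows": int(len(df)), "exclusions": {}}

    def _rows_with(raters):
        cols = [_RATER_COLS[r] for r in raters]
        mask = np.ones(len(df), dtype=bool)
        for c in cols:
            mask &= df[c].notna().to_numpy() & (df[c].astype(str).str.strip() != "").to_numpy()
        return df.loc[mask], int((~mask).sum())

    # accuracy of nurse and tool vs the reference standard
    sub, excluded = _rows_with(["nurse", "tool", "oph1", "oph2"])
    report["exclusions"]["accuracy"] = excluded
    ref = np.array(
        [
            reference_urgent(a, b)
            for a, b in zip(sub["oph1_grade"], sub["oph2_grade"])
        ]
    )
    consensus_codes = np.maximum(
        grades_to_codes(sub["oph1_grade"]), grades_to_codes(sub["oph2_grade"])
    )  # the *less* urgent of the pair: urgent only when both reviewers agree
    combined_codes = np.minimum(
        grades_to_codes(sub["oph1_grade"]), grades_to_codes(sub["oph2_grade"])
    )
    report["reference"] = {"n_urgent": int(ref.sum()), "n": int(ref.size)}

    report["accuracy"] = {}
    report["percent_agreement_urgent"] = {}
    confusions = {}
    for rater in ("nurse", "tool"):
        pred = is_urgent(sub[_RATER_COLS[rater]])
        c = confusions[rater] = confusion(pred, ref)
        report["accuracy"][rater] = {
            "table": {"tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn},
            **accuracy(c).to_dict(),
        }
        report["percent_agreement_urgent"][rater] = percent_agreement_urgent(
            sub[_RATER_COLS[rater]], ref
        )

    # paired McNemar on sensitivity and specificity where per-patient pairs exist
    nurse_u = is_urgent(sub["nurse_grade"])
    tool_u = is_urgent(sub["tool_grade"])
    report["mcnemar"] = {}
    for label, mask in (("sensitivity", ref), ("specificity", ~ref)):
        b = int(np.sum(nurse_u[mask] & ~tool_u[mask]))
        c_ = int(np.sum(~nurse_u[mask] & tool_u[mask]))
        if label == "specificity":
            # concordance with the reference on negatives = non-urgent calls
            b = int(np.sum(~nurse_u[mask] & tool_u[mask]))
            c_ = int(np.sum(nurse_u[mask] & ~tool_u[mask]))
        if b + c_ > 0:
            stat, p = mcnemar_cc(b, c_)
            report["mcnemar"][label] = {"b": b, "c": c_, "statistic": stat, "p_value": p}
        else:
            report["mcnemar"][label] = {"b": b, "c": c_, "statistic": None, "p_value": None}

    # down-rating of urgent nurse dispositions
    report["downrate_vs_nurse"] = {}
    try:
        n_down, prop = downrate_analysis(
            ["ABCD"[c - 1] for c in consensus_codes], sub["nurse_grade"]
        )
        report["downrate_vs_nurse"]["ophthalmologist_consensus"] = {
            "n_downrated": n_down,
            "proportion": prop,
        }
        n_down, prop = downrate_analysis(sub["tool_grade"], sub["nurse_grade"])
        report["downrate_vs_nurse"]["tool"] = {"n_downrated": n_down, "proportion": prop}
    except ValueError:
        report["downrate_vs_nurse"] = None

    # over/under-estimation relative to the combined (more-urgent-wins) grade
    report["over_under_vs_reference"] = {}
    for rater in ("nurse", "tool"):
        over, under = over_under_estimation(sub[_RATER_COLS[rater]], combined_codes)
        report["over_under_vs_reference"][rater] = {"over": over, "under": under}

    # pairwise ordinal agreement
    report["agreement"] = {}
    for r1, r2 in _KAPPA_PAIRS:
        pair, excluded = _rows_with([r1, r2])
        tab = crosstab(pair[_RATER_COLS[r1]], pair[_RATER_COLS[r2]])
        pa = percent_agreement_urgent(
            pair[_RATER_COLS[r1]], is_urgent(pair[_RATER_COLS[r2]])
        )
        try:
            res = weighted_kappa(
                tab,
                percent_agreement=pa,
                ci_method=kappa_ci_method,
                bootstrap_reps=bootstrap_reps,
                rng=rng,
            )
            report["agreement"][f"{r1}_vs_{r2}"] = {**res.to_dict(), "excluded": excluded}
        except ValueError as exc:
            report["agreement"][f"{r1}_vs_{r2}"] = {"error": str(exc), "excluded": excluded}

    # service-disposition analyses
    outcome_cols = ["imaging", "tests", "prescription", "procedure"]
    if all(col in df.columns for col in outcome_cols):
        flags = df[outcome_cols].dropna()
        if len(flags):
            suitable = (flags.astype(float) == 0).all(axis=1)
            report["community_care_suitable"] = {
                "n": int(suitable.sum()),
                "proportion": float(suitable.mean()),
                "n_with_outcome": int(len(flags)),
            }
    if "tool_service" in df.columns:
        from .chart import ServiceRoute

        routes = df["tool_service"].dropna()
        routes = routes[routes.astype(str).str.strip() != ""]
        ess = routes.map(lambda s: ServiceRoute(s).ess_eligible)
        if len(routes):
            report["ess_suitable"] = {
                "n": int(ess.sum()),
                "proportion": float(ess.mean()),
            }

    # descriptive summaries
    if "likert" in df.columns and df["likert"].notna().any():
        mean, sd, n_l, top2 = likert_summary(df["likert"].tolist())
        report["likert"] = {"mean": mean, "sd": sd, "n": n_l, "prop_top2": top2}
    if "duration_s" in df.columns and df["duration_s"].notna().any():
        dur = df["duration_s"].dropna().astype(float) / 60.0
        report["duration_minutes"] = {
            "mean": float(dur.mean()),
            "sd": float(dur.std(ddof=1)) if len(dur) > 1 else None,
            "n": int(len(dur)),
            "min": float(dur.min()),
            "max": float(dur.max()),
        }

    return report
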