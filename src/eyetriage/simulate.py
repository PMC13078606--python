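"""Synthetic triage cohorts with recoverable ground truth.

Two kinds of synthetic data are produced here:

* :func:`generate_cohort` — a generative model: each patient has a latent
  true urgency grade drawn from a prevalence vector; each rater (nurse,
  tool, two ophthalmologist reviewers) assigns a grade drawn independently
  from the row of that rater's 4x4 confusion matrix indexed by the latent
  grade.  Presenting concern, Likert acceptability score, test duration and
  clinic-outcome flags are drawn from separate marginal models.  Every
  statistic in :mod:`eyetriage.stats` therefore has a known target.

* :func:`fixture_study_cohort` — a deterministic 282-row cohort
  reconstructed from a published evaluation's printed counts, realising the
  nurse and tool 2x2 accuracy tables, the reference-standard margin, the
  down-rating figures and the service-disposition margins jointly.  It is a
  marginal reconstruction, not patient data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .stats import Confusion2x2

__all__ = [
    "SimulationConfig",
    "generate_cohort",
    "study_like_config",
    "fixture_study_tables",
    "fixture_study_cohort",
    "GRADE_LETTERS",
    "CONCERNS",
]

GRADE_LETTERS = ["A", "B", "C", "D"]
CONCERNS = [
    "red_or_painful_eye",
    "painless_visual_disturbance",
    "eye_injury",
    "eyelid_problem",
]
RATERS = ["nurse", "tool", "oph1", "oph2"]

COHORT_COLUMNS = [
    "patient_id",
    "nurse_grade",
    "tool_grade",
    "oph1_grade",
    "oph2_grade",
    "concern",
    "imaging",
    "tests",
    "prescription",
    "procedure",
    "likert",
    "duration_s",
]


@dataclass
class SimulationConfig:
    """Parameters of the generative cohort model.

    ``rater_models`` maps each rater to a row-stochastic 4x4 matrix: entry
    (t, a) is the probability that a patient whose latent grade has code
    t+1 is assigned the grade with code a+1.  ``outcome_model`` maps each
    latent grade letter to the four per-flag probabilities (imaging, other
    tests, prescription, procedure).
    """

    n: int
    prevalence: np.ndarray                      # over latent grades A-D
    rater_models: Dict[str, np.ndarray]
    concern_mix: np.ndarray                     # over the 4 presenting concerns
    likert_model: Optional[np.ndarray] = None   # categorical over 1..5
    likert_response_rate: float = 1.0
    duration_model: Optional[Tuple[float, float, float, float]] = None
    # (mu, sigma) of log-minutes plus (lower, upper) truncation in minutes
    outcome_model: Optional[Dict[str, Tuple[float, float, float, float]]] = None
    seed: int = 0

    def validate(self) -> None:
        errors = []
        if self.n < 1:
            errors.append("n must be >= 1")
        prev = np.asarray(self.prevalence, dtype=float)
        if prev.shape != (4,) or abs(prev.sum() - 1) > 1e-9 or (prev < 0).any():
            errors.append("prevalence must be a length-4 probability vector")
        mix = np.asarray(self.concern_mix, dtype=float)
        if mix.shape != (4,) or abs(mix.sum() - 1) > 1e-9 or (mix < 0).any():
            errors.append("concern_mix must be a length-4 probability vector")
        for rater in RATERS:
            if rater not in self.rater_models:
                errors.append(f"rater_models missing {rater!r}")
                continue
            m = np.asarray(self.rater_models[rater], dtype=float)
            if m.shape != (4, 4) or (m < 0).any() or np.abs(m.sum(axis=1) - 1).max() > 1e-9:
                errors.append(f"rater_models[{rater!r}] must be a row-stochastic 4x4 matrix")
        if self.likert_model is not None:
            lm = np.asarray(self.likert_model, dtype=float)
            if lm.shape != (5,) or abs(lm.sum() - 1) > 1e-9 or (lm < 0).any():
                errors.append("likert_model must be a length-5 probability vector")
        if not 0 <= self.likert_response_rate <= 1:
            errors.append("likert_response_rate must be in [0, 1]")
        if errors:
            raise ValueError("invalid simulation config: " + "; ".join(errors))


def generate_cohort(config: SimulationConfig, seed: Optional[int] = None):
    """Draw a synthetic cohort; returns ``(cohort DataFrame, latent truth)``.

    The cohort table uses the evaluation CSV dialect (grades as letters,
    outcome flags as 0/1, empty = missing).  The latent truth table carries
    the per-patient true grade so simulation studies can score recovery.
    Reproducible: the same ``(config, seed)`` gives byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n

    latent = rng.choice(4, size=n, p=np.asarray(config.prevalence, dtype=float))

    data: dict = {"patient_id": [f"P{i+1:05d}" for i in range(n)]}
    for rater in RATERS:
        m = np.asarray(config.rater_models[rater], dtype=float)
        # vectorised row-wise categorical draw via inverse-CDF
        cdf = np.cumsum(m, axis=1)
        u = rng.random(n)
        assigned = (u[:, None] > cdf[latent]).sum(axis=1)
        data[f"{rater}_grade"] = [GRADE_LETTERS[a] for a in assigned]

    concern_idx = rng.choice(4, size=n, p=np.asarray(config.concern_mix, dtype=float))
    data["concern"] = [CONCERNS[i] for i in concern_idx]

    if config.outcome_model is not None:
        flags = np.empty((n, 4), dtype=np.int64)
        probs = np.array(
            [config.outcome_model[GRADE_LETTERS[t]] for t in range(4)], dtype=float
        )
        flags = (rng.random((n, 4)) < probs[latent]).astype(np.int64)
        for j, col in enumerate(["imaging", "tests", "prescription", "procedure"]):
            data[col] = flags[:, j]
    else:
        for col in ["imaging", "tests", "prescription", "procedure"]:
            data[col] = np.full(n, np.nan)

    if config.likert_model is not None:
        scores = rng.choice(np.arange(1, 6), size=n, p=np.asarray(config.likert_model, float))
        responded = rng.random(n) < config.likert_response_rate
        data["likert"] = np.where(responded, scores.astype(float), np.nan)
    else:
        data["likert"] = np.full(n, np.nan)

    if config.duration_model is not None:
        mu, sigma, lo, hi = config.duration_model
        minutes = np.exp(rng.normal(mu, sigma, size=n))
        # redraw outside the plausible range rather than clipping, so the
        # truncation does not pile mass on the bounds
        for _ in range(100):
            bad = (minutes < lo) | (minutes > hi)
            if not bad.any():
                break
            minutes[bad] = np.exp(rng.normal(mu, sigma, size=int(bad.sum())))
        data["duration_s"] = np.round(minutes * 60.0, 1)
    else:
        data["duration_s"] = np.full(n, np.nan)

    cohort = pd.DataFrame(data, columns=COHORT_COLUMNS)
    truth = pd.DataFrame(
        {
            "patient_id": data["patient_id"],
            "true_grade": [GRADE_LETTERS[t] for t in latent],
        }
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# Study-like configuration

def _banded_matrix(p_urgent_given_urgent: float, p_urgent_given_nonurgent: float) -> np.ndarray:
    """4x4 rater matrix with prescribed urgent-band row sums.

    Within-band splits are fixed at plausible values; only the band-level
    sums (the dichotomous operating point) are calibrated.
    """
    pu, pn = p_urgent_given_urgent, p_urgent_given_nonurgent
    return np.array(
        [
            # true A: mostly graded A/B
            [0.60 * pu, 0.40 * pu, 0.80 * (1 - pu), 0.20 * (1 - pu)],
            # true B
            [0.25 * pu, 0.75 * pu, 0.80 * (1 - pu), 0.20 * (1 - pu)],
            # true C: urgent assignments with prob pn (overtriage)
            [0.30 * pn, 0.70 * pn, 0.85 * (1 - pn), 0.15 * (1 - pn)],
            # true D
            [0.20 * pn, 0.80 * pn, 0.45 * (1 - pn), 0.55 * (1 - pn)],
        ]
    )


def study_like_config(n: int = 282, seed: int = 0) -> SimulationConfig:
    """A configuration whose margins match the published evaluation.

    * latent urgent-band prevalence 76/282, split (21, 55, 159, 47)/282
      over A-D;
    * presenting-concern mix (50.0, 41.1, 6.4, 2.5)%;
    * nurse band-level operating point sensitivity 0.855 / specificity
      0.228, tool 0.763 / 0.641, embedded as band row sums of the 4x4
      matrices;
    * ophthalmologist reviewer matrices are band-faithful (they never cross
      the urgent boundary relative to the latent grade), so the combined
      at-least-one-urgent reference standard recovers the latent band
      exactly and estimated sensitivity/specificity converge to the
      configured operating points;
    * Likert distribution moment-matched to mean 4.21 / SD 0.82 with top-2
      mass 0.804; duration lognormal matched to mean 5.6 / SD 2.4 minutes,
      truncated to the observed range (9 s to 20.7 min).
    """
    oph1 = np.array(
        [
            [0.70, 0.30, 0.00, 0.00],
            [0.30, 0.70, 0.00, 0.00],
            [0.00, 0.00, 0.80, 0.20],
            [0.00, 0.00, 0.30, 0.70],
        ]
    )
    oph2 = np.array(
        [
            [0.30, 0.40, 0.20, 0.10],
            [0.10, 0.30, 0.40, 0.20],
            [0.00, 0.00, 0.70, 0.30],
            [0.00, 0.00, 0.20, 0.80],
        ]
    )
    # lognormal moment match: mean 5.6, sd 2.4 minutes
    cv2 = (2.4 / 5.6) ** 2
    sigma2 = float(np.log1p(cv2))
    mu = float(np.log(5.6) - sigma2 / 2)
    return SimulationConfig(
        n=n,
        prevalence=np.array([21, 55, 159, 47]) / 282.0,
        rater_models={
            "nurse": _banded_matrix(0.855, 1 - 0.228),
            "tool": _banded_matrix(0.763, 1 - 0.641),
            "oph1": oph1,
            "oph2": oph2,
        },
        concern_mix=np.array([0.500, 0.411, 0.064, 0.025]),
        likert_model=np.array([0.004, 0.022, 0.170, 0.368, 0.436]),
        likert_response_rate=209 / 282,
        duration_model=(mu, float(np.sqrt(sigma2)), 9 / 60, 20.7),
        outcome_model={
            "A": (0.50, 0.40, 0.50, 0.15),
            "B": (0.50, 0.40, 0.50, 0.15),
            "C": (0.12, 0.10, 0.25, 0.01),
            "D": (0.12, 0.10, 0.25, 0.01),
        },
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Deterministic study-marginal fixture

def fixture_study_tables() -> Tuple[Confusion2x2, Confusion2x2]:
    """The nurse and tool 2x2 accuracy tables implied by the printed counts.

    Sensitivities 65/76 (nurse) and 58/76 (tool); specificities 47/206 and
    132/206; false positives/negatives follow by subtraction within the
    reference margins (76 urgent, 206 non-urgent, n=282).
    """
    nurse = Confusion2x2(tp=65, fp=206 - 47, fn=76 - 65, tn=47)
    tool = Confusion2x2(tp=58, fp=206 - 132, fn=76 - 58, tn=132)
    return nurse, tool


# Joint dichotomy cell counts (nurse-urgent, tool-urgent, reference-urgent)
# solved from the printed margins: nurse 2x2 (65,159,11,47), tool 2x2
# (58,74,18,132), tool down-rating 93/224 of nurse-urgent dispositions.
_FIXTURE_CELLS = [
    # (nurse_urgent, tool_urgent, ref_urgent, count)
    (True, True, True, 57),
    (True, True, False, 74),
    (True, False, True, 8),
    (False, True, True, 1),
    (True, False, False, 85),
    (False, True, False, 0),
    (False, False, True, 10),
    (False, False, False, 47),
]
_N_BOTH_OPH_URGENT = 21  # both-reviewer-urgent subset, all nurse-urgent


def fixture_study_cohort() -> pd.DataFrame:
    """Deterministic 282-row cohort realising the printed study margins.

    Jointly realised: both 2x2 accuracy tables (hence the sensitivities,
    specificities and urgent-dichotomy percent agreements), the 76/282
    reference-urgent margin, the 21-patient both-reviewer-urgent subset
    (hence the 203/224 reviewer down-rating), the 93/224 tool down-rating,
    the presenting-concern mix, the 131/282 community-care-suitable outcome
    margin, the 256/282 tool ESS-route margin, and a 209-response Likert
    column with 168 top-2 ratings and mean 4.21.  Grade letters within the
    urgent/non-urgent bands are schematic (B for urgent, C for non-urgent
    assignments) because the full A-D distributions are unpublished; the
    printed over/under-estimation percentages are mutually inconsistent
    with the 2x2 tables and are deliberately not realised.
    """
    rows = []
    n_both = 0
    for nurse_u, tool_u, ref_u, count in _FIXTURE_CELLS:
        for _ in range(count):
            nurse = "B" if nurse_u else "C"
            tool = "B" if tool_u else "C"
            if ref_u:
                oph1 = "B"
                # the both-urgent subset lives in the nurse+tool+ref cell
                if nurse_u and tool_u and n_both < _N_BOTH_OPH_URGENT:
                    oph2 = "B"
                    n_both += 1
                else:
                    oph2 = "C"
            else:
                oph1, oph2 = "C", "C"
            rows.append((nurse, tool, oph1, oph2, tool_u, ref_u))

    n = len(rows)
    assert n == 282 and n_both == _N_BOTH_OPH_URGENT

    # presenting concerns to the printed mix (independent of grades: the
    # joint concern-by-grade distribution is unpublished)
    concerns = (
        ["red_or_painful_eye"] * 141
        + ["painless_visual_disturbance"] * 116
        + ["eye_injury"] * 18
        + ["eyelid_problem"] * 7
    )

    # outcome flags: 131 rows need nothing (community-care suitable); the
    # rest get a prescription flag.  Allocated to non-reference-urgent rows
    # first, as clinically coherent a placement as the margins allow.
    order = sorted(range(n), key=lambda i: (rows[i][5], i))  # non-urgent first
    suitable = set(order[:131])

    # tool service routes: 256/282 ESS-eligible.  Non-ESS routes go to the
    # first 26 tool-urgent rows (ED/EEC); remaining tool-urgent rows get the
    # community urgent eye service, tool-non-urgent rows optometry/pharmacy.
    service = [""] * n
    n_non_ess = 0
    n_pharm = 0
    for i, r in enumerate(rows):
        if r[4] and n_non_ess < 26:
            service[i] = "ED" if n_non_ess < 5 else "EEC"
            n_non_ess += 1
        elif r[4]:
            service[i] = "community_urgent_eye_service"
        else:
            service[i] = "pharmacy" if n_pharm < 40 else "private_optometry"
            n_pharm += 1

    # Likert: 209 responses, counts (1, 3, 37, 78, 90) over scores 1..5
    # -> mean 880/209 = 4.21, SD 0.817, top-2 168/209 = 80.4%
    likert_values = [1.0] * 1 + [2.0] * 3 + [3.0] * 37 + [4.0] * 78 + [5.0] * 90
    likert = likert_values + [np.nan] * (n - len(likert_values))

    df = pd.DataFrame(
        {
            "patient_id": [f"S{i+1:04d}" for i in range(n)],
            "nurse_grade": [r[0] for r in rows],
            "tool_grade": [r[1] for r in rows],
            "oph1_grade": [r[2] for r in rows],
            "oph2_grade": [r[3] for r in rows],
            "concern": concerns,
            "imaging": [0] * n,
            "tests": [0] * n,
            "prescription": [0 if i in suitable else 1 for i in range(n)],
            "procedure": [0] * n,
            "likert": likert,
            "duration_s": [np.nan] * n,
        },
        columns=COHORT_COLUMNS,
    )
    df["tool_service"] = service
    return df
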