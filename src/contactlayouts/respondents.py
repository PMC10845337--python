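"""Synthetic participants for the contact-layout study.

Real cohorts (crowdworkers, biomedical scientists) are not shipped with
this package; this module simulates respondents with the behavioral
structure the analysis battery is designed to detect:

* layout-dependent accuracy (``p_correct``);
* a propensity, when wrong, to pick the *inverted* answer — the contact
  read from the opposite chain direction (``p_invert_given_error``);
* erroneous choices biased toward contacts whose segments are closer in
  sequence than the correct pair (``separation_bias``) and toward
  distractors near the correct contact (``proximity_bias``), producing the
  negatively skewed inter-segment distance distributions seen in humans;
* response times that decay exponentially to a plateau over the course of
  the survey, with multiplicative lognormal noise;
* explicit answer memory on duplicated questions (``memory``), which
  drives the duplicate-consistency score independently of accuracy.

On questions whose contact is self-symmetric (no inverted answer exists) a
misreading of the chain direction still lands on the correct answer, so
such questions are easier in practice; ``symmetric_error_scale`` < 1
captures this by shrinking their error probability.  At its default of 1
the error rate is uniform across questions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .metrics import SchemaError, min_distance
from .stimuli import (
    Contact,
    Question,
    StudyConfig,
    build_question,
    build_survey,
    enumerate_contacts,
)

__all__ = [
    "ParticipantProfile",
    "CohortSpec",
    "sample_choice",
    "sample_rt",
    "simulate_study",
    "write_response_table",
    "read_response_table",
    "calibrate_inversion_probability",
    "expected_inversion_share",
    "uniform_random_profile",
    "mturk_cohorts",
    "expert_cohorts",
]

RESPONSE_COLUMNS = [
    "participant_id",
    "layout",
    "presentation_index",
    "model_id",
    "is_repeat",
    "chosen_a",
    "chosen_b",
    "correct_a",
    "correct_b",
    "inverted_a",
    "inverted_b",
    "rt_seconds",
]


@dataclass(frozen=True)
class ParticipantProfile:
    """Behavioral parameters of one simulated respondent.

    Parameters
    ----------
    p_correct
        Probability of answering a question correctly.
    p_invert_given_error
        Given an error on a question that has an inverted answer, the
        probability of choosing that inverted answer.
    separation_bias
        gamma >= 0; erroneous distractor choices are down-weighted by
        exp(gamma * (separation(d) - separation(correct))), skewing errors
        toward contacts closer in sequence than the truth.
    proximity_bias
        beta >= 0; distractors are down-weighted by exp(beta * MinDistance
        to the correct contact), favoring near misses.
    rt_plateau, rt_amplitude, rt_decay
        Learning-curve parameters, seconds / seconds / per-presentation:
        the noise-free response time at presentation k is
        plateau + amplitude * exp(-decay * (k - 1)).
    rt_noise_sd
        Log-scale standard deviation of the multiplicative lognormal
        response-time noise.
    memory
        rho, the probability of repeating one's earlier answer verbatim
        when a question is presented the second time.
    symmetric_error_scale
        Multiplier on the error probability for questions whose contact is
        self-symmetric (no inverted answer); 1.0 leaves the error rate
        uniform across questions.
    """

    p_correct: float = 0.85
    p_invert_given_error: float = 0.6
    separation_bias: float = 0.5
    proximity_bias: float = 0.5
    rt_plateau: float = 8.0
    rt_amplitude: float = 8.0
    rt_decay: float = 0.15
    rt_noise_sd: float = 0.35
    memory: float = 0.7
    symmetric_error_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("p_correct", "p_invert_given_error", "memory"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.rt_plateau <= 0:
            raise ValueError("rt_plateau must be positive")
        for name in ("separation_bias", "proximity_bias", "rt_amplitude",
                     "rt_decay", "rt_noise_sd", "symmetric_error_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    """One layout arm of the study: a layout label, a cohort size and the
    behavioral profile shared by its participants."""

    layout: str
    n_participants: int
    profile: ParticipantProfile

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")


def _error_probability(profile: ParticipantProfile, question: Question) -> float:
    p_err = 1.0 - profile.p_correct
    if question.inverted is None:
        p_err = min(1.0, p_err * profile.symmetric_error_scale)
    return p_err


def sample_choice(
    profile: ParticipantProfile,
    question: Question,
    prior_answer: Optional[Contact],
    rng: np.random.Generator,
    n_segments: int = 8,
) -> Contact:
    """Draw one answer to a question.

    On a duplicate presentation (``prior_answer`` given) the earlier
    answer is repeated with probability ``memory``; otherwise the answer
    is redrawn from scratch.  A fresh draw is correct with the question's
    success probability; an error goes to the inverted answer with
    probability ``p_invert_given_error`` when one exists, and otherwise to
    a distractor drawn with weight
    exp(-beta * MinDistance(d, correct) - gamma * (sep(d) - sep(correct))).
    """
    if prior_answer is not None and rng.random() < profile.memory:
        return prior_answer
    if rng.random() >= _error_probability(profile, question):
        return question.correct
    if question.inverted is not None and rng.random() < profile.p_invert_given_error:
        return question.inverted
    distractors = [
        o for o in question.options if o != question.correct and o != question.inverted
    ]
    sep0 = question.correct.separation
    logw = np.array(
        [
            -profile.proximity_bias * min_distance(d, question.correct, n_segments)
            - profile.separation_bias * (d.separation - sep0)
            for d in distractors
        ]
    )
    w = np.exp(logw - logw.max())
    return distractors[rng.choice(len(distractors), p=w / w.sum())]


def sample_rt(
    profile: ParticipantProfile, presentation_index: int, rng: np.random.Generator
) -> float:
    """Draw a response time for the k-th presentation.

    The noise-free time decays exponentially from plateau + amplitude at
    the first presentation to the plateau, modelling task learning;
    multiplicative lognormal noise keeps draws positive and right-skewed.
    """
    if presentation_index < 1:
        raise ValueError("presentation_index is 1-based")
    base = profile.rt_plateau + profile.rt_amplitude * math.exp(
        -profile.rt_decay * (presentation_index - 1)
    )
    noise = math.exp(rng.normal(0.0, profile.rt_noise_sd)) if profile.rt_noise_sd else 1.0
    return base * noise


def _simulate_participant(
    pid: str,
    spec: CohortSpec,
    questions: Sequence[Question],
    config: StudyConfig,
    rng: np.random.Generator,
) -> list[dict]:
    survey = build_survey(spec.layout, questions, config, rng)
    answers: dict[str, Contact] = {}
    rows = []
    for pres in survey.presentations:
        q = pres.question
        prior = answers.get(q.model_id) if pres.is_repeat else None
        chosen = sample_choice(spec.profile, q, prior, rng, config.n_segments)
        answers[q.model_id] = chosen
        rows.append(
            {
                "participant_id": pid,
                "layout": spec.layout,
                "presentation_index": pres.presentation_index,
                "model_id": q.model_id,
                "is_repeat": pres.is_repeat,
                "chosen_a": chosen.a,
                "chosen_b": chosen.b,
                "correct_a": q.correct.a,
                "correct_b": q.correct.b,
                "inverted_a": q.inverted.a if q.inverted else pd.NA,
                "inverted_b": q.inverted.b if q.inverted else pd.NA,
                "rt_seconds": sample_rt(spec.profile, pres.presentation_index, rng),
            }
        )
    return rows


def simulate_study(
    cohorts: Sequence[CohortSpec],
    config: StudyConfig,
    seed: int,
    rt_outlier: Optional[float] = None,
) -> pd.DataFrame:
    """Simulate a full study and return the tidy response table.

    A single question bank is built from the enumerated contact family and
    shared by every cohort — as in the study design, all layout arms see
    the same questions and only the rendering differs.  Every participant
    receives an independently randomized survey (question order, duplicate
    placement and option order all reshuffled) and answers it under the
    cohort's behavioral profile.  The result is fully reproducible from
    ``seed``.

    ``rt_outlier``, when given, overwrites the response time of the very
    first simulated response with that value — a hook for exercising the
    slow-response filter the analysis applies.
    """
    root = np.random.SeedSequence(seed)
    bank_rng = np.random.default_rng(root.spawn(1)[0])
    questions = [
        build_question(c, config, bank_rng)
        for c in enumerate_contacts(config.n_segments, config.min_separation)
    ]
    frames = []
    for spec in cohorts:
        cohort_ss = root.spawn(1)[0]
        for pi, pss in enumerate(cohort_ss.spawn(spec.n_participants)):
            pid = f"{spec.layout}_{pi + 1:03d}"
            frames.extend(
                _simulate_participant(
                    pid, spec, questions, config, np.random.default_rng(pss)
                )
            )
    table = pd.DataFrame(frames, columns=RESPONSE_COLUMNS)
    table["inverted_a"] = table["inverted_a"].astype("Int64")
    table["inverted_b"] = table["inverted_b"].astype("Int64")
    if rt_outlier is not None and len(table):
        table.loc[0, "rt_seconds"] = float(rt_outlier)
    return table


# ---------------------------------------------------------------------------
# response-table I/O


def write_response_table(table: pd.DataFrame, path: Union[str, Path]) -> Path:
    """Write a response table as RFC-4180 CSV (UTF-8, header row)."""
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_response_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a response table CSV.

    Checks the column contract, contact ordering (a < b), positive
    response times, and that every chosen/correct pair is well formed.
    """
    table = pd.read_csv(
        path,
        dtype={
            "participant_id": str,
            "layout": str,
            "model_id": str,
        },
    )
    missing = [c for c in RESPONSE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"response table is missing columns: {missing}")
    if len(table) == 0:
        raise SchemaError("response table contains no data rows")
    table["inverted_a"] = table["inverted_a"].astype("Int64")
    table["inverted_b"] = table["inverted_b"].astype("Int64")
    table["is_repeat"] = table["is_repeat"].astype(bool)
    for prefix in ("chosen", "correct"):
        a, b = table[f"{prefix}_a"], table[f"{prefix}_b"]
        bad = ~(a < b) | (a < 1)
        if bad.any():
            raise SchemaError(
                f"{prefix} contacts must satisfy 1 <= a < b "
                f"(first bad row index {int(bad.idxmax())})"
            )
    if (table["rt_seconds"] <= 0).any():
        raise SchemaError("rt_seconds must be strictly positive")
    if table["inverted_a"].isna().ne(table["inverted_b"].isna()).any():
        raise SchemaError("inverted_a/inverted_b must be both present or both absent")
    return table


# ---------------------------------------------------------------------------
# calibration and presets


def expected_inversion_share(
    p_invert_given_error: float,
    n_invertible: int = 12,
    n_symmetric: int = 3,
    symmetric_error_scale: float = 1.0,
) -> float:
    """Expected share of errors classified as inversions under the choice
    model, with errors spread across questions in proportion to their
    error probability."""
    weight_inv = n_invertible
    weight_sym = n_symmetric * symmetric_error_scale
    return weight_inv * p_invert_given_error / (weight_inv + weight_sym)


def calibrate_inversion_probability(
    target_share: float,
    n_invertible: int = 12,
    n_symmetric: int = 3,
    symmetric_error_scale: float = 1.0,
) -> float:
    """Invert :func:`expected_inversion_share` for a target error share.

    Because every error on a symmetric-contact question is by definition
    not an inversion, the achievable share is capped at
    n_invertible / (n_invertible + n_symmetric * symmetric_error_scale);
    shares above the cap (such as the ~85% seen for circular layouts in
    practice) require ``symmetric_error_scale`` < 1.
    """
    cap = n_invertible / (n_invertible + n_symmetric * symmetric_error_scale)
    if not (0.0 <= target_share <= 1.0):
        raise ValueError("target_share must lie in [0, 1]")
    if target_share > cap:
        raise ValueError(
            f"target share {target_share:.3f} exceeds the achievable cap "
            f"{cap:.3f}; lower symmetric_error_scale"
        )
    return target_share * (n_invertible + n_symmetric * symmetric_error_scale) / (
        n_invertible
    )


def uniform_random_profile(n_options: int = 5) -> ParticipantProfile:
    """The "random clicker": every option equally likely, no answer memory.

    With five options this respondent's expected duplicate-consistency is
    exactly 1/5 — the 20% guessing baseline used as the exclusion
    threshold.  Implemented as p_correct = 1/n, conditional inversion
    probability 1/(n-1), and zero bias weights, which makes every option
    slot exactly equally likely.
    """
    return ParticipantProfile(
        p_correct=1.0 / n_options,
        p_invert_given_error=1.0 / (n_options - 1),
        separation_bias=0.0,
        proximity_bias=0.0,
        memory=0.0,
        rt_plateau=5.0,
        rt_amplitude=0.0,
        rt_decay=0.0,
        rt_noise_sd=0.3,
        symmetric_error_scale=1.0,
    )


# Per-layout profiles emulating the published crowdsourced cohort: the
# circular layout is decoded most accurately and most consistently, almost
# all of its errors are 3D-model inversions, and its learning curve is
# nearly flat; the two matrix layouts are slower, less consistent, and
# their errors skew toward too-small separations.
_MTURK_SHARED = dict(rt_noise_sd=0.35, proximity_bias=0.5, symmetric_error_scale=0.5)

_MTURK_PROFILES = {
    "circular": ParticipantProfile(
        p_correct=0.93,
        p_invert_given_error=calibrate_inversion_probability(0.845, symmetric_error_scale=0.5),
        separation_bias=0.3,
        rt_plateau=6.0,
        rt_amplitude=4.0,
        rt_decay=0.5,
        memory=0.75,
        **_MTURK_SHARED,
    ),
    "half_matrix": ParticipantProfile(
        p_correct=0.82,
        p_invert_given_error=calibrate_inversion_probability(0.566, symmetric_error_scale=0.5),
        separation_bias=0.8,
        rt_plateau=9.0,
        rt_amplitude=10.0,
        rt_decay=0.12,
        memory=0.55,
        **_MTURK_SHARED,
    ),
    "matrix": ParticipantProfile(
        p_correct=0.80,
        p_invert_given_error=calibrate_inversion_probability(0.605, symmetric_error_scale=0.5),
        separation_bias=0.8,
        rt_plateau=9.5,
        rt_amplitude=12.0,
        rt_decay=0.12,
        memory=0.68,
        **_MTURK_SHARED,
    ),
}

# Expert profiles: higher accuracy throughout, no layout effect on
# consistency, matrix fastest despite being least accurate, and a lower
# share of inversion errors on the matrix layouts than for crowdworkers.
_EXPERT_SHARED = dict(rt_noise_sd=0.3, proximity_bias=0.5, symmetric_error_scale=0.5, memory=0.8)

_EXPERT_PROFILES = {
    "circular": ParticipantProfile(
        p_correct=0.95,
        p_invert_given_error=calibrate_inversion_probability(0.80, symmetric_error_scale=0.5),
        separation_bias=0.4,
        rt_plateau=5.6,
        rt_amplitude=4.0,
        rt_decay=0.3,
        **_EXPERT_SHARED,
    ),
    "half_matrix": ParticipantProfile(
        p_correct=0.94,
        p_invert_given_error=calibrate_inversion_probability(0.45, symmetric_error_scale=0.5),
        separation_bias=0.8,
        rt_plateau=7.5,
        rt_amplitude=6.0,
        rt_decay=0.15,
        **_EXPERT_SHARED,
    ),
    "matrix": ParticipantProfile(
        p_correct=0.86,
        p_invert_given_error=calibrate_inversion_probability(0.45, symmetric_error_scale=0.5),
        separation_bias=0.8,
        rt_plateau=5.2,
        rt_amplitude=4.0,
        rt_decay=0.3,
        **_EXPERT_SHARED,
    ),
}


def mturk_cohorts(n_participants: int = 50) -> list[CohortSpec]:
    """Crowdsourced-study preset: 50 participants per layout (4,500
    responses with the default 30-presentation survey)."""
    return [
        CohortSpec(layout, n_participants, profile)
        for layout, profile in _MTURK_PROFILES.items()
    ]


def expert_cohorts(n_participants: int = 10) -> list[CohortSpec]:
    """Expert-study preset: 10 participants per layout (900 responses)."""
    return [
        CohortSpec(layout, n_participants, profile)
        for layout, profile in _EXPERT_PROFILES.items()
    ]
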