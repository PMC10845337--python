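"""Stimulus and survey construction for the contact-layout perceptual study.

The study presents segmented 3D models of a cylindrical chain in which
exactly one pair of segments touches (a *spatial contact*), and asks
participants to identify that pair from a multiple-choice list rendered in
one of three 2D layouts.  This module builds the contact family, the
*inverted answer* distractors (the answer that would be correct if the chain
were read in the opposite direction), the five-option questions, and the
randomized per-participant presentation order with duplicated questions for
consistency scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Contact",
    "StudyConfig",
    "Question",
    "Presentation",
    "SurveyDesign",
    "enumerate_contacts",
    "invert_contact",
    "build_question",
    "build_survey",
    "survey_to_frame",
]

LAYOUTS = ("circular", "half_matrix", "matrix")


class InvalidConfigError(ValueError):
    """Raised when a study configuration violates its invariants."""


@dataclass(frozen=True, order=True)
class Contact:
    """An unordered pair of 1-based segment indices, stored ascending."""

    a: int
    b: int

    def __post_init__(self) -> None:
        if not (1 <= self.a < self.b):
            raise ValueError(f"contact must satisfy 1 <= a < b, got {self.a}-{self.b}")

    @property
    def separation(self) -> int:
        """Sequence separation |b - a| between the two segments."""
        return self.b - self.a

    def __str__(self) -> str:
        return f"{self.a}-{self.b}"

    @classmethod
    def parse(cls, text: str) -> "Contact":
        """Parse a contact from an ``"a-b"`` string."""
        parts = text.strip().split("-")
        if len(parts) != 2:
            raise ValueError(f"cannot parse contact from {text!r}")
        return cls(int(parts[0]), int(parts[1]))


@dataclass(frozen=True)
class StudyConfig:
    """Design constants of the perceptual study.

    Defaults encode the published design: an eight-segment chain, contacts
    separated by at least three segments (which yields the 15-model stimulus
    family), five answer options per question, and every question repeated
    once.  The animation constants describe the rocking-motion renders of
    the 3D stimuli; they are carried for provenance only and no rendering is
    performed here.
    """

    n_segments: int = 8
    min_separation: int = 3
    n_options: int = 5
    repeat_fraction: float = 1.0
    layouts: tuple[str, ...] = LAYOUTS
    rocking_amplitude_deg: float = 3.0
    rocking_frames: int = 136
    rocking_duration_s: float = 3.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_segments < 2:
            raise InvalidConfigError("n_segments must be >= 2")
        if not (1 <= self.min_separation <= self.n_segments - 1):
            raise InvalidConfigError(
                "min_separation must lie in [1, n_segments - 1]"
            )
        if self.n_options < 2:
            raise InvalidConfigError("n_options must be >= 2")
        if not (0.0 <= self.repeat_fraction <= 1.0):
            raise InvalidConfigError("repeat_fraction must lie in [0, 1]")
        unknown = set(self.layouts) - set(LAYOUTS)
        if unknown:
            raise InvalidConfigError(f"unknown layouts: {sorted(unknown)}")


@dataclass(frozen=True)
class Question:
    """One multiple-choice question: a correct contact plus distractors."""

    model_id: str
    correct: Contact
    options: tuple[Contact, ...]
    inverted: Optional[Contact] = None

    def __post_init__(self) -> None:
        if len(set(self.options)) != len(self.options):
            raise ValueError("options must be pairwise distinct")
        if self.correct not in self.options:
            raise ValueError("options must include the correct contact")
        if self.inverted is not None:
            if self.inverted == self.correct:
                raise ValueError("inverted answer cannot equal the correct one")
            if self.inverted not in self.options:
                raise ValueError("options must include the inverted answer")


@dataclass(frozen=True)
class Presentation:
    presentation_index: int  # 1-based position in the survey
    question: Question
    is_repeat: bool
    option_order: tuple[int, ...]  # permutation of option slots

    def presented_options(self) -> tuple[Contact, ...]:
        return tuple(self.question.options[i] for i in self.option_order)


@dataclass(frozen=True)
class SurveyDesign:
    layout: str
    presentations: tuple[Presentation, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.presentations)


def enumerate_contacts(n_segments: int, min_separation: int) -> list[Contact]:
    """Enumerate all admissible contacts on an ``n_segments`` chain.

    Returns every pair with sequence separation at least ``min_separation``,
    sorted by (separation, first segment).  With eight segments and minimum
    separation 3 this yields the study's 15-model family.  A separation
    larger than any pair can span yields an empty list.
    """
    if n_segments < 2 or min_separation < 1:
        raise InvalidConfigError("n_segments >= 2 and min_separation >= 1 required")
    out = [
        Contact(a, a + sep)
        for sep in range(min_separation, n_segments)
        for a in range(1, n_segments - sep + 1)
    ]
    return out


def invert_contact(contact: Contact, n_segments: int) -> Optional[Contact]:
    """Contact obtained by reading the chain in the opposite direction.

    Each segment ``i`` maps to ``n_segments + 1 - i``; the result is
    re-normalized ascending.  Returns ``None`` when the contact is
    self-symmetric (the inverted reading coincides with the original), in
    which case the question has no inverted answer.
    """
    if contact.b > n_segments:
        raise ValueError(f"contact {contact} exceeds n_segments={n_segments}")
    a, b = n_segments + 1 - contact.b, n_segments + 1 - contact.a
    inv = Contact(a, b)
    return None if inv == contact else inv


def build_question(
    correct: Contact, config: StudyConfig, rng: np.random.Generator
) -> Question:
    """Assemble one question: correct answer, inverted answer when it
    exists, and random distractors drawn without replacement from the
    admissible contact family."""
    pool = enumerate_contacts(config.n_segments, config.min_separation)
    if correct not in pool:
        raise ValueError(f"correct contact {correct} is not in the stimulus family")
    inverted = invert_contact(correct, config.n_segments)
    fixed = [correct] + ([inverted] if inverted is not None else [])
    candidates = [c for c in pool if c not in fixed]
    n_fill = config.n_options - len(fixed)
    if n_fill < 0:
        raise InvalidConfigError("n_options too small for correct + inverted answers")
    if n_fill > len(candidates):
        raise InvalidConfigError(
            f"distractor pool of size {len(candidates)} cannot fill "
            f"{n_fill} option slots"
        )
    picks = rng.choice(len(candidates), size=n_fill, replace=False)
    distractors = [candidates[i] for i in picks]
    return Question(
        model_id=str(correct),
        correct=correct,
        options=tuple(fixed + distractors),
        inverted=inverted,
    )


def build_survey(
    layout: str,
    questions: Sequence[Question],
    config: StudyConfig,
    rng: np.random.Generator,
) -> SurveyDesign:
    """Randomize a presentation list for one participant.

    Duplicates ``ceil(repeat_fraction * len(questions))`` questions (all of
    them at the default repeat fraction of 1), shuffles the combined list,
    and draws an independent option-order permutation for every
    presentation.  ``is_repeat`` marks the second occurrence of a model in
    presentation order; no spacing constraint is imposed on the duplicates.
    """
    if not questions:
        raise ValueError("questions must be non-empty")
    n_repeat = ceil(config.repeat_fraction * len(questions))
    repeat_idx = rng.choice(len(questions), size=n_repeat, replace=False)
    pending = list(questions) + [questions[i] for i in repeat_idx]
    order = rng.permutation(len(pending))

    seen: set[str] = set()
    presentations = []
    for pos, j in enumerate(order, start=1):
        q = pending[j]
        option_order = tuple(int(i) for i in rng.permutation(len(q.options)))
        presentations.append(
            Presentation(
                presentation_index=pos,
                question=q,
                is_repeat=q.model_id in seen,
                option_order=option_order,
            )
        )
        seen.add(q.model_id)
    return SurveyDesign(layout=layout, presentations=tuple(presentations))


def survey_to_frame(design: SurveyDesign) -> pd.DataFrame:
    """Serialize a survey design to a tidy table, one row per presentation.

    Columns: layout, presentation_index, model_id, is_repeat, the option
    contacts in presented order (semicolon-joined ``a-b`` strings), and the
    slot (1-based) of the correct option in that presented order.
    """
    rows = []
    for p in design.presentations:
        presented = p.presented_options()
        rows.append(
            {
                "layout": design.layout,
                "presentation_index": p.presentation_index,
                "model_id": p.question.model_id,
                "is_repeat": p.is_repeat,
                "options": ";".join(str(c) for c in presented),
                "correct_slot": presented.index(p.question.correct) + 1,
            }
        )
    return pd.DataFrame(rows)
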