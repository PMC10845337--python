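"""Participant- and answer-level scores for the contact-layout study.

Implements the complete scoring battery: duplicate-question consistency,
accuracy, the inversion / inverted-missing / other error taxonomy, the
inter-segment distance score (chosen separation minus correct separation),
the MinDistance score (minimum total segment displacement over the direct
and inverted readings of the chosen contact), pair-averaged learning
curves, and the response-time and low-consistency filters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .stimuli import Contact, invert_contact

__all__ = [
    "ERROR_CLASSES",
    "consistency_score",
    "consistency_by_participant",
    "classify_error",
    "intersegment_distance",
    "min_distance",
    "participant_summaries",
    "learning_curve",
    "filter_responses",
    "filter_participants",
    "classify_table",
    "error_breakdown",
    "ErrorBreakdown",
]

ERROR_CLASSES = ("correct", "inversion", "inverted_missing", "other")


class SchemaError(ValueError):
    """Raised when a response table violates the documented schema."""


# ---------------------------------------------------------------------------
# answer-level scores


def classify_error(
    chosen: Contact, correct: Contact, inverted: Optional[Contact]
) -> str:
    """Classify one answer.

    ``correct`` when the chosen contact matches the truth; ``inversion``
    when it matches the inverted answer (the participant read the 3D model
    backwards but decoded the layout correctly); ``inverted_missing`` for
    any error on a question whose contact is self-symmetric and therefore
    has no inverted answer; ``other`` for all remaining errors.
    """
    if chosen == correct:
        return "correct"
    if inverted is not None and chosen == inverted:
        return "inversion"
    if inverted is None:
        return "inverted_missing"
    return "other"


def intersegment_distance(chosen: Contact, correct: Contact) -> int:
    """Chosen-pair separation minus correct-pair separation.

    Zero for correct answers and for pure inversion errors (inversion
    preserves separation); negative when the chosen segments are closer in
    sequence than the correct ones.
    """
    return chosen.separation - correct.separation


def min_distance(chosen: Contact, correct: Contact, n_segments: int) -> int:
    """Minimum total segment displacement between chosen and correct.

    The direct term sums |a_chosen - a_correct| + |b_chosen - b_correct|
    over the ascending endpoints; the inverted term first maps each chosen
    segment i to n_segments + 1 - i, re-sorts ascending, and sums the same
    differences.  The score is the smaller of the two, so it is 0 exactly
    when the chosen contact is the correct one or its inversion — it
    measures layout-decoding error without penalizing 3D-model inversions.
    """
    direct = abs(chosen.a - correct.a) + abs(chosen.b - correct.b)
    ia, ib = sorted((n_segments + 1 - chosen.a, n_segments + 1 - chosen.b))
    inverted = abs(ia - correct.a) + abs(ib - correct.b)
    return min(direct, inverted)


# ---------------------------------------------------------------------------
# table helpers

_REQUIRED_COLUMNS = [
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


def _require_schema(table: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"response table is missing columns: {missing}")


def _row_contacts(row) -> tuple[Contact, Contact, Optional[Contact]]:
    chosen = Contact(int(row.chosen_a), int(row.chosen_b))
    correct = Contact(int(row.correct_a), int(row.correct_b))
    inverted = (
        None
        if pd.isna(row.inverted_a)
        else Contact(int(row.inverted_a), int(row.inverted_b))
    )
    return chosen, correct, inverted


def classify_table(table: pd.DataFrame, n_segments: int = 8) -> pd.DataFrame:
    """Annotate a response table with the three answer-level scores.

    Adds ``error_class``, ``intersegment_distance`` and ``min_distance``
    columns; the input is not modified.
    """
    _require_schema(table)
    out = table.copy()
    cls, isd, md = [], [], []
    for row in out.itertuples(index=False):
        chosen, correct, inverted = _row_contacts(row)
        cls.append(classify_error(chosen, correct, inverted))
        isd.append(intersegment_distance(chosen, correct))
        md.append(min_distance(chosen, correct, n_segments))
    out["error_class"] = cls
    out["intersegment_distance"] = isd
    out["min_distance"] = md
    return out


# ---------------------------------------------------------------------------
# participant-level scores


def consistency_score(responses: pd.DataFrame) -> float:
    """Fraction of duplicated questions a participant answered identically.

    ``responses`` holds one participant's rows.  Every model presented
    twice contributes one pair; the score is the share of pairs whose two
    chosen contacts agree.  A model appearing more than twice violates the
    survey design and raises :class:`SchemaError`.
    """
    _require_schema(responses)
    counts = responses["model_id"].value_counts()
    if (counts > 2).any():
        bad = counts[counts > 2].index.tolist()
        raise SchemaError(f"model(s) presented more than twice: {bad}")
    paired = counts[counts == 2].index
    if len(paired) == 0:
        raise SchemaError("no duplicated questions; consistency is undefined")
    agree = 0
    grouped = responses.set_index("model_id")
    for mid in paired:
        rows = grouped.loc[mid]
        if (
            rows["chosen_a"].iloc[0] == rows["chosen_a"].iloc[1]
            and rows["chosen_b"].iloc[0] == rows["chosen_b"].iloc[1]
        ):
            agree += 1
    return agree / len(paired)


def consistency_by_participant(table: pd.DataFrame) -> pd.Series:
    """Vectorized duplicate-consistency for every participant in a table.

    Equivalent to applying :func:`consistency_score` per participant, but
    computed with grouped first/last comparisons so cohort-scale and
    Monte-Carlo-scale tables stay cheap.
    """
    _require_schema(table)
    srt = table.sort_values(["participant_id", "model_id", "presentation_index"])
    g = srt.groupby(["participant_id", "model_id"], sort=False)
    size = g.size()
    if (size > 2).any():
        bad = size[size > 2].index.tolist()
        raise SchemaError(f"model(s) presented more than twice: {bad[:5]}")
    first, last = g.head(1), g.tail(1)
    agree = (
        (first["chosen_a"].to_numpy() == last["chosen_a"].to_numpy())
        & (first["chosen_b"].to_numpy() == last["chosen_b"].to_numpy())
    )
    agree = pd.Series(agree, index=size.index)[size == 2]
    if agree.empty:
        raise SchemaError("no duplicated questions; consistency is undefined")
    return agree.groupby(level=0).mean()


def participant_summaries(table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant consistency, accuracy and response count.

    Accuracy here is the raw share of correct answers over the rows given;
    the analysis pipeline recomputes it after the exclusion filters.
    """
    _require_schema(table)
    consistency = consistency_by_participant(table)
    correct = (table["chosen_a"] == table["correct_a"]) & (
        table["chosen_b"] == table["correct_b"]
    )
    acc = correct.groupby(table["participant_id"]).mean()
    meta = table.groupby("participant_id").agg(
        layout=("layout", "first"), n_responses=("layout", "size")
    )
    out = pd.DataFrame(
        {
            "participant_id": meta.index,
            "layout": meta["layout"].to_numpy(),
            "consistency": consistency.reindex(meta.index).to_numpy(),
            "accuracy": acc.reindex(meta.index).to_numpy(),
            "n_responses": meta["n_responses"].to_numpy(),
        }
    ).reset_index(drop=True)
    out["excluded"] = False
    out["exclusion_reason"] = ""
    return out.sort_values(["participant_id"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# filters


def filter_responses(
    table: pd.DataFrame, rt_cutoff: float = 5000.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop responses slower than ``rt_cutoff`` seconds.

    Returns the filtered table and a removal log (one row per removed
    response).  The default cutoff targets the pathological
    interrupted-session outliers, not the tail of honest slow answers.
    """
    _require_schema(table)
    mask = table["rt_seconds"] > rt_cutoff
    removed = table.loc[mask, ["participant_id", "layout", "presentation_index",
                               "model_id", "rt_seconds"]].copy()
    removed["reason"] = f"rt_seconds > {rt_cutoff:g}"
    return table.loc[~mask].copy(), removed.reset_index(drop=True)


def filter_participants(
    summaries: pd.DataFrame, consistency_threshold: float = 0.20
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude participants at or below the consistency threshold.

    The bound is inclusive: a score equal to the threshold (the
    five-option uniform-guessing baseline of 20%) is excluded.  Returns
    the annotated summaries and the exclusion log; callers drop the
    excluded participants' responses downstream.
    """
    out = summaries.copy()
    mask = out["consistency"] <= consistency_threshold
    out.loc[mask, "excluded"] = True
    out.loc[mask, "exclusion_reason"] = (
        f"consistency <= {consistency_threshold:g}"
    )
    log = out.loc[mask, ["participant_id", "layout", "consistency",
                         "exclusion_reason"]].reset_index(drop=True)
    return out, log


# ---------------------------------------------------------------------------
# cohort-level summaries


def learning_curve(responses: pd.DataFrame) -> pd.DataFrame:
    """Mean response time per question rank, duplicates pair-averaged.

    For each participant the two response times of each duplicated model
    are averaged into a single pair value, placed at the rank of the
    pair's earlier presentation index; with 15 unique questions this
    yields curve points 1 through 15 rather than 1 through 30.  Returns
    one row per rank with the cohort mean, standard deviation, standard
    error and the number of contributing participants.
    """
    _require_schema(responses)
    per_participant = []
    for pid, grp in responses.groupby("participant_id", sort=True):
        pairs = (
            grp.groupby("model_id")
            .agg(rt=("rt_seconds", "mean"), first_seen=("presentation_index", "min"))
            .sort_values("first_seen", kind="mergesort")
            .reset_index()
        )
        pairs["rank"] = np.arange(1, len(pairs) + 1)
        pairs["participant_id"] = pid
        per_participant.append(pairs[["participant_id", "rank", "rt"]])
    tidy = pd.concat(per_participant, ignore_index=True)
    curve = (
        tidy.groupby("rank")["rt"]
        .agg(mean_rt="mean", sd_rt="std", n="size")
        .reset_index()
    )
    curve["sem_rt"] = curve["sd_rt"] / np.sqrt(curve["n"])
    return curve


@dataclass(frozen=True)
class ErrorBreakdown:
    """Per-layout error composition and score distributions.

    ``fractions`` — share of each error class among incorrect answers;
    ``eq_scores_errors`` — tidy inter-segment distance values, incorrect
    answers only; ``min_distance_all`` — tidy MinDistance values over all
    answers; ``n_errors`` — incorrect-answer sample size per layout.
    """

    fractions: pd.DataFrame
    eq_scores_errors: pd.DataFrame
    min_distance_all: pd.DataFrame
    n_errors: pd.Series


def error_breakdown(table: pd.DataFrame, n_segments: int = 8) -> ErrorBreakdown:
    """Error taxonomy fractions and score distributions by layout.

    Class fractions and the inter-segment distance distribution are
    computed over incorrect answers only; the MinDistance distribution is
    computed over all answers.  Layouts with zero errors report empty
    fraction rows (n = 0) rather than dividing by zero.
    """
    scored = classify_table(table, n_segments=n_segments)
    errors = scored[scored["error_class"] != "correct"]

    frac_rows = []
    n_errors = {}
    for layout, grp in scored.groupby("layout", sort=True):
        err = grp[grp["error_class"] != "correct"]
        n_errors[layout] = len(err)
        for cls in ERROR_CLASSES[1:]:
            frac_rows.append(
                {
                    "layout": layout,
                    "error_class": cls,
                    "fraction": (
                        float((err["error_class"] == cls).mean())
                        if len(err)
                        else np.nan
                    ),
                    "n_errors": len(err),
                }
            )
    return ErrorBreakdown(
        fractions=pd.DataFrame(frac_rows),
        eq_scores_errors=errors[["layout", "intersegment_distance"]].reset_index(
            drop=True
        ),
        min_distance_all=scored[["layout", "min_distance"]].reset_index(drop=True),
        n_errors=pd.Series(n_errors, name="n_errors"),
    )
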