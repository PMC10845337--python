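"""Inferential battery for the contact-layout study.

Consistency and response times are compared across layouts with a one-way
ANOVA followed by Tukey's HSD post hoc; accuracy with pairwise Pearson
chi-squared tests of independence (no continuity correction); and the
inter-segment distance / MinDistance score distributions with a
tie-corrected Kruskal-Wallis omnibus followed by Dunn's pairwise z tests.
All families of pairwise p-values are adjusted for multiple testing
(Benjamini-Hochberg by default) with significance declared at alpha =
0.05.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import metrics

__all__ = [
    "TestResult",
    "adjust_pvalues",
    "anova_tukey",
    "pairwise_chi2",
    "kruskal_dunn",
    "run_full_analysis",
    "AnalysisReport",
]

_ADJUST_METHODS = {"bh": "fdr_bh", "holm": "holm", "bonferroni": "bonferroni"}


@dataclass(frozen=True)
class TestResult:
    """One inferential comparison with raw and adjusted p-values."""

    method: str
    groups: tuple[str, ...]
    statistic: float
    df: Optional[float]
    p_raw: float
    p_adjusted: float
    alpha: float = 0.05
    note: str = ""

    @property
    def significant(self) -> bool:
        return bool(self.p_adjusted < self.alpha) if np.isfinite(self.p_adjusted) else False

    def __post_init__(self) -> None:
        for name in ("p_raw", "p_adjusted"):
            p = getattr(self, name)
            if np.isfinite(p) and not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {p}")


def _results_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "method": r.method,
                "groups": " vs ".join(r.groups),
                "statistic": r.statistic,
                "df": r.df,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "significant": r.significant,
                "note": r.note,
            }
            for r in results
        ]
    )


def adjust_pvalues(p_values: Sequence[float], method: str = "bh") -> np.ndarray:
    """Adjust a family of p-values for multiple testing.

    ``method`` is one of ``bh`` (Benjamini-Hochberg step-up, the default),
    ``holm`` or ``bonferroni``.  Adjusted values are monotone in the input
    ranks and never smaller than the raw values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    try:
        sm_method = _ADJUST_METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown adjustment method {method!r}; choose from {sorted(_ADJUST_METHODS)}"
        ) from None
    return multipletests(p, method=sm_method)[1]


# ---------------------------------------------------------------------------
# test families


def _as_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    return {k: np.asarray(v, dtype=float) for k, v in groups.items()}


def anova_tukey(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> tuple[TestResult, list[TestResult]]:
    """One-way ANOVA omnibus plus all-pairs Tukey HSD post hoc.

    Tukey p-values control the family-wise error rate by construction, so
    the pairwise results carry them as both raw and adjusted values.  A
    degenerate input with zero variance everywhere and equal group means
    reports F = 0, p = 1.
    """
    g = _as_groups(groups)
    if len(g) < 2 or any(len(v) < 2 for v in g.values()):
        raise ValueError("need >= 2 groups with >= 2 values each")
    labels = list(g)
    values = list(g.values())
    allv = np.concatenate(values)
    n = allv.size
    df = (len(g) - 1, n - len(g))
    if np.ptp(allv) == 0.0:
        omnibus = TestResult("anova", tuple(labels), 0.0, df[0], 1.0, 1.0, alpha,
                             note="degenerate: all values identical")
        pairs = [
            TestResult("tukey_hsd", (a, b), 0.0, None, 1.0, 1.0, alpha,
                       note="degenerate: all values identical")
            for a, b in itertools.combinations(labels, 2)
        ]
        return omnibus, pairs
    f_stat, p = stats.f_oneway(*values)
    omnibus = TestResult("anova", tuple(labels), float(f_stat), df[0], float(p), float(p), alpha)
    hsd = stats.tukey_hsd(*values)
    pairs = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        p_ij = float(hsd.pvalue[i, j])
        pairs.append(
            TestResult(
                "tukey_hsd",
                (labels[i], labels[j]),
                float(hsd.statistic[i, j]),
                None,
                p_ij,
                p_ij,
                alpha,
                note="Tukey HSD p-values are family-wise adjusted by construction",
            )
        )
    return omnibus, pairs


def pairwise_chi2(
    counts: Mapping[str, tuple[int, int]],
    method: str = "bh",
    alpha: float = 0.05,
) -> list[TestResult]:
    """Pairwise Pearson chi-squared tests of independence on 2x2 tables.

    ``counts`` maps each group label to its (correct, incorrect) counts.
    No continuity correction is applied (cell counts in the designed uses
    are far above 5).  A pair with a zero margin is reported as
    not-applicable (NaN statistic and p, never significant).  Raw p-values
    are adjusted across the pairs with ``method``.
    """
    labels = list(counts)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    raw = []
    for a, b in itertools.combinations(labels, 2):
        tab = np.array([counts[a], counts[b]], dtype=float)
        if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
            raw.append((a, b, np.nan, np.nan, "not applicable: zero margin"))
            continue
        chi2, p, dof, _ = stats.chi2_contingency(tab, correction=False)
        raw.append((a, b, float(chi2), float(p), ""))
    valid = [r for r in raw if np.isfinite(r[3])]
    adj = adjust_pvalues([r[3] for r in valid], method) if valid else np.array([])
    adj_iter = iter(adj)
    out = []
    for a, b, chi2, p, note in raw:
        p_adj = float(next(adj_iter)) if np.isfinite(p) else np.nan
        out.append(TestResult("chi2_independence", (a, b), chi2, 1, p, p_adj, alpha, note))
    return out


def _dunn_pairwise(
    g: dict[str, np.ndarray], method: str, alpha: float
) -> list[TestResult]:
    labels = list(g)
    sizes = {k: v.size for k, v in g.items()}
    allv = np.concatenate(list(g.values()))
    n = allv.size
    ranks = stats.rankdata(allv)
    mean_ranks = {}
    start = 0
    for k in labels:
        mean_ranks[k] = ranks[start:start + sizes[k]].mean()
        start += sizes[k]
    # tie correction: sum(t^3 - t) over tie groups
    _, tie_counts = np.unique(allv, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    raw = []
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        if se == 0.0:
            raw.append((a, b, 0.0, 1.0))
            continue
        z = (mean_ranks[a] - mean_ranks[b]) / se
        raw.append((a, b, float(z), float(2.0 * stats.norm.sf(abs(z)))))
    adj = adjust_pvalues([r[3] for r in raw], method)
    return [
        TestResult("dunn", (a, b), z, None, p, float(pa), alpha)
        for (a, b, z, p), pa in zip(raw, adj)
    ]


def kruskal_dunn(
    groups: Mapping[str, Sequence[float]],
    method: str = "bh",
    alpha: float = 0.05,
) -> tuple[TestResult, list[TestResult]]:
    """Tie-corrected Kruskal-Wallis omnibus plus Dunn pairwise post hoc.

    Dunn's test compares mean ranks from the pooled ranking with the
    normal approximation and the standard tie correction; its p-values
    are adjusted across pairs with ``method``.  Fully tied input (every
    value identical) reports H = 0, p = 1.
    """
    g = _as_groups(groups)
    if len(g) < 2:
        raise ValueError("need >= 2 groups")
    labels = list(g)
    allv = np.concatenate(list(g.values()))
    if np.ptp(allv) == 0.0:
        omnibus = TestResult("kruskal_wallis", tuple(labels), 0.0, len(g) - 1, 1.0, 1.0,
                             alpha, note="degenerate: all values identical")
        pairs = [
            TestResult("dunn", (a, b), 0.0, None, 1.0, 1.0, alpha,
                       note="degenerate: all values identical")
            for a, b in itertools.combinations(labels, 2)
        ]
        return omnibus, pairs
    h_stat, p = stats.kruskal(*g.values())
    omnibus = TestResult(
        "kruskal_wallis", tuple(labels), float(h_stat), len(g) - 1, float(p), float(p), alpha
    )
    return omnibus, _dunn_pairwise(g, method, alpha)


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class AnalysisReport:
    """Bundle of tables produced by :func:`run_full_analysis`.

    ``tables`` maps stable names to tidy DataFrames (test results, curves,
    summaries, logs); ``write`` persists them as CSV together with the
    figures and a plain-text summary.
    """

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    n_responses: dict[str, int] = field(default_factory=dict)

    def summary_text(self) -> str:
        lines = ["contact-layout study analysis", "=" * 31, ""]
        for key, val in self.n_responses.items():
            lines.append(f"{key}: {val}")
        lines.append("")
        for name in sorted(self.tables):
            df = self.tables[name]
            lines.append(f"[{name}] ({len(df)} rows)")
            lines.append(df.to_string(index=False, max_rows=40))
            lines.append("")
        return "\n".join(lines)

    def write(self, outdir, figures: bool = True) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "summary.txt").write_text(self.summary_text(), encoding="utf-8")
        if figures:
            from .plots import report_figures

            report_figures(self, outdir)


def run_full_analysis(
    table: pd.DataFrame,
    n_segments: int = 8,
    rt_cutoff: float = 5000.0,
    consistency_threshold: float = 0.20,
    adjust_method: str = "bh",
    alpha: float = 0.05,
) -> AnalysisReport:
    """Run the complete analysis battery on a response table.

    Order of operations: slow-response filter; per-participant consistency;
    exclusion of participants at or below the guessing threshold; then, on
    the retained responses — consistency ANOVA + Tukey, accuracy pairwise
    chi-squared, response-time ANOVA + Tukey, pair-averaged learning
    curves with their own ANOVA + Tukey, the error taxonomy, and
    Kruskal-Wallis + Dunn on the inter-segment distance scores (errors
    only) and MinDistance scores (all answers).

    Duplicated presentations exist to measure consistency and learning;
    because a participant frequently repeats an earlier answer verbatim,
    the two answers of a pair are strongly correlated and would overcount
    evidence in tests that assume independent responses.  The accuracy and
    score-distribution analyses therefore use each question's first
    presentation only; response times keep all presentations (their noise
    is independent across presentations and the learning analysis needs
    both).
    """
    if len(table) == 0:
        raise metrics.SchemaError("response table contains no data rows")
    report = AnalysisReport()
    report.n_responses["n_responses_input"] = len(table)

    filtered, removals = metrics.filter_responses(table, rt_cutoff=rt_cutoff)
    report.tables["filter_rt_removals"] = removals
    report.n_responses["n_responses_after_rt_filter"] = len(filtered)

    summaries = metrics.participant_summaries(filtered)
    summaries, exclusions = metrics.filter_participants(
        summaries, consistency_threshold=consistency_threshold
    )
    report.tables["participant_summaries"] = summaries
    report.tables["participant_exclusions"] = exclusions
    kept_ids = set(summaries.loc[~summaries["excluded"], "participant_id"])
    kept = filtered[filtered["participant_id"].isin(kept_ids)].copy()
    report.n_responses["n_participants_kept"] = len(kept_ids)
    report.n_responses["n_responses_analyzed"] = len(kept)

    kept_sum = summaries[~summaries["excluded"]]
    layouts = sorted(kept["layout"].unique())

    # consistency across layouts
    cons_groups = {
        lay: kept_sum.loc[kept_sum["layout"] == lay, "consistency"].to_numpy()
        for lay in layouts
    }
    omni, pairs = anova_tukey(cons_groups, alpha=alpha)
    report.tables["consistency_tests"] = _results_frame([omni] + pairs)

    # accuracy across layouts: first presentations only (see docstring)
    first = kept[~kept["is_repeat"].astype(bool)]
    correct_mask = (first["chosen_a"] == first["correct_a"]) & (
        first["chosen_b"] == first["correct_b"]
    )
    counts = {
        lay: (
            int(correct_mask[first["layout"] == lay].sum()),
            int((~correct_mask)[first["layout"] == lay].sum()),
        )
        for lay in layouts
    }
    report.tables["accuracy_counts"] = pd.DataFrame(
        [
            {"layout": lay, "n_correct": c, "n_incorrect": i,
             "accuracy": c / (c + i) if c + i else np.nan}
            for lay, (c, i) in counts.items()
        ]
    )
    report.tables["accuracy_tests"] = _results_frame(
        pairwise_chi2(counts, method=adjust_method, alpha=alpha)
    )

    # response times across layouts
    rt_groups = {
        lay: kept.loc[kept["layout"] == lay, "rt_seconds"].to_numpy()
        for lay in layouts
    }
    omni, pairs = anova_tukey(rt_groups, alpha=alpha)
    report.tables["response_time_tests"] = _results_frame([omni] + pairs)
    report.tables["response_time_means"] = pd.DataFrame(
        [{"layout": lay, "mean_rt": v.mean(), "median_rt": np.median(v)}
         for lay, v in rt_groups.items()]
    )

    # learning curves (pair-averaged times) per layout
    curves = []
    pair_groups = {}
    for lay in layouts:
        cohort = kept[kept["layout"] == lay]
        curve = metrics.learning_curve(cohort)
        curve.insert(0, "layout", lay)
        curves.append(curve)
        pair_times = (
            cohort.groupby(["participant_id", "model_id"])["rt_seconds"]
            .mean()
            .to_numpy()
        )
        pair_groups[lay] = pair_times
    report.tables["learning_curves"] = pd.concat(curves, ignore_index=True)
    omni, pairs = anova_tukey(pair_groups, alpha=alpha)
    report.tables["learning_curve_tests"] = _results_frame([omni] + pairs)

    # error taxonomy and score distributions: first presentations only
    breakdown = metrics.error_breakdown(first, n_segments=n_segments)
    report.tables["error_fractions"] = breakdown.fractions
    report.tables["intersegment_distance_errors"] = breakdown.eq_scores_errors
    report.tables["min_distance_all"] = breakdown.min_distance_all

    isd_groups = {
        lay: grp["intersegment_distance"].to_numpy()
        for lay, grp in breakdown.eq_scores_errors.groupby("layout")
        if len(grp) >= 2
    }
    if len(isd_groups) >= 2:
        omni, pairs = kruskal_dunn(isd_groups, method=adjust_method, alpha=alpha)
        report.tables["intersegment_distance_tests"] = _results_frame([omni] + pairs)
    md_groups = {
        lay: grp["min_distance"].to_numpy()
        for lay, grp in breakdown.min_distance_all.groupby("layout")
    }
    if len(md_groups) >= 2:
        omni, pairs = kruskal_dunn(md_groups, method=adjust_method, alpha=alpha)
        report.tables["min_distance_tests"] = _results_frame([omni] + pairs)

    return report
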