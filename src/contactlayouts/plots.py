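"""Report figures: cohort overview and error-analysis panels."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

_LAYOUT_COLORS = {"circular": "#1b9e77", "half_matrix": "#d95f02", "matrix": "#7570b3"}


def _color(layout: str) -> str:
    return _LAYOUT_COLORS.get(layout, "#666666")


def overview_figure(report, path: Path) -> None:
    """Four panels: consistency, accuracy, response times (log scale) and
    pair-averaged learning curves, by layout."""
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    summaries = report.tables["participant_summaries"]
    kept = summaries[~summaries["excluded"]]
    layouts = sorted(kept["layout"].unique())

    ax = axes[0, 0]
    data = [kept.loc[kept["layout"] == lay, "consistency"] for lay in layouts]
    box = ax.boxplot(data, tick_labels=layouts, patch_artist=True)
    for patch, lay in zip(box["boxes"], layouts):
        patch.set_facecolor(_color(lay))
    ax.set_ylabel("consistency")
    ax.set_title("duplicate-question consistency")

    ax = axes[0, 1]
    acc = report.tables["accuracy_counts"].set_index("layout").loc[layouts]
    ax.bar(layouts, acc["accuracy"], color=[_color(l) for l in layouts])
    ax.set_ylim(0, 1)
    ax.set_ylabel("accuracy")
    ax.set_title("overall accuracy")

    ax = axes[1, 0]
    curves = report.tables["learning_curves"]
    rt_means = report.tables["response_time_means"].set_index("layout").loc[layouts]
    ax.bar(layouts, rt_means["mean_rt"], color=[_color(l) for l in layouts])
    ax.set_yscale("log")
    ax.set_ylabel("mean response time (s, log scale)")
    ax.set_title("response time")

    ax = axes[1, 1]
    for lay in layouts:
        sub = curves[curves["layout"] == lay]
        ax.errorbar(sub["rank"], sub["mean_rt"], yerr=sub["sem_rt"],
                    label=lay, color=_color(lay), marker="o", ms=3)
    ax.set_xlabel("question (duplicates pair-averaged)")
    ax.set_ylabel("mean response time (s)")
    ax.set_title("learning curves")
    ax.legend(fontsize=8)

    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def error_figure(report, path: Path) -> None:
    """Three panels: error-class composition, inter-segment distance
    distribution over errors, MinDistance distribution over all answers."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    fractions = report.tables["error_fractions"]
    layouts = sorted(fractions["layout"].unique())

    ax = axes[0]
    bottoms = np.zeros(len(layouts))
    for cls, shade in [("inversion", 0.9), ("inverted_missing", 0.6), ("other", 0.3)]:
        vals = [
            float(fractions.loc[(fractions["layout"] == lay)
                                & (fractions["error_class"] == cls), "fraction"].iloc[0])
            for lay in layouts
        ]
        vals = np.nan_to_num(np.array(vals))
        ax.bar(layouts, vals, bottom=bottoms, label=cls, alpha=shade, color="#555555")
        bottoms += vals
    ax.set_ylabel("fraction of incorrect answers")
    ax.set_title("error classes")
    ax.legend(fontsize=8)

    ax = axes[1]
    isd = report.tables["intersegment_distance_errors"]
    for lay in layouts:
        vals = isd.loc[isd["layout"] == lay, "intersegment_distance"]
        if len(vals):
            bins = np.arange(vals.min() - 0.5, vals.max() + 1.5)
            ax.hist(vals, bins=bins, histtype="step", density=True,
                    label=lay, color=_color(lay))
    ax.set_xlabel("inter-segment distance score (errors only)")
    ax.set_title("inter-segment distance")
    ax.legend(fontsize=8)

    ax = axes[2]
    md = report.tables["min_distance_all"]
    for lay in layouts:
        vals = md.loc[md["layout"] == lay, "min_distance"]
        bins = np.arange(-0.5, vals.max() + 1.5)
        ax.hist(vals, bins=bins, histtype="step", density=True,
                label=lay, color=_color(lay))
    ax.set_xlabel("MinDistance (all answers)")
    ax.set_title("MinDistance")
    ax.legend(fontsize=8)

    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def report_figures(report, outdir: Path) -> None:
    outdir = Path(outdir)
    overview_figure(report, outdir / "overview.svg")
    error_figure(report, outdir / "errors.svg")
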