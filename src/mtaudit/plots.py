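"""Static figure rendering for titration audits.

Longitudinal three-track plots (counts and doses per visit), cycle-specific
summary measure (CSSM) plots, cohort treatment-intensity scatters with the
desired-intensity region shaded, and cumulative-incidence plots for time to
first dose increase.  Figures are written to SVG or PNG; SVG metadata dates
are suppressed so identical inputs give byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "mtaudit"  # reproducible SVG ids

import matplotlib.pyplot as plt
import pandas as pd

from .intensity import CycleSummary, PatientSummary, visit_intensities
from .model import PatientCourse, ProtocolRules

__all__ = [
    "plot_progression",
    "plot_cssm",
    "plot_cohort_scatter",
    "plot_cumulative_incidence",
]


def _save(fig, path: Path) -> Path:
    path = Path(path)
    kwargs = {}
    if path.suffix.lower() == ".svg":
        kwargs["metadata"] = {"Date": None}
    fig.savefig(path, bbox_inches="tight", **kwargs)
    plt.close(fig)
    return path


def plot_progression(
    course: PatientCourse, rules: ProtocolRules, path: str | Path
) -> Path:
    """Three-track longitudinal plot: ANC, 6MP and MTX doses over the course.

    Dashed horizontals mark the ANC target range and the BSA-scaled
    protocol-recommended dose of each drug.
    """
    weeks = course.weeks
    fig, axes = plt.subplots(3, 1, sharex=True, figsize=(9, 7))

    anc_w = [(w, v.anc) for w, v in zip(weeks, course.visits) if v.anc is not None]
    if anc_w:
        axes[0].plot(*zip(*anc_w), marker=".", lw=1, color="tab:blue")
    for y in rules.anc_target_range:
        axes[0].axhline(y, ls="--", lw=0.8, color="grey")
    axes[0].set_ylabel("ANC (10$^9$/L)")

    mp_protocol = [rules.mp_protocol_weekly_dose(v.bsa) for v in course.visits]
    axes[1].step(weeks, [v.mp_dose for v in course.visits], where="post",
                 color="tab:red")
    axes[1].plot(weeks, mp_protocol, ls="--", lw=0.8, color="grey")
    axes[1].set_ylabel("6MP (mg/week)")

    mtx_protocol = [rules.mtx_protocol_weekly_dose(v.bsa) for v in course.visits]
    axes[2].step(weeks, [v.mtx_dose for v in course.visits], where="post",
                 color="tab:green")
    axes[2].plot(weeks, mtx_protocol, ls="--", lw=0.8, color="grey")
    axes[2].set_ylabel("MTX (mg/week)")
    axes[2].set_xlabel("week of maintenance")
    axes[2].set_xlim(0, max(course.mt_end_week, weeks[-1]))
    fig.suptitle(course.patient_id)
    return _save(fig, Path(path))


def plot_cssm(
    cycles: Sequence[CycleSummary],
    overall: PatientSummary,
    rules: ProtocolRules,
    path: str | Path,
) -> Path:
    """Cycle-specific summary measure: combined DI vs weighted-mean ANC.

    One greyscale point per cycle (darker = later), a red point for the
    whole course, dashed lines at the ANC target range and the DI
    threshold.
    """
    fig, ax = plt.subplots(figsize=(6, 5))
    n = max(len(cycles), 1)
    for i, c in enumerate(cycles):
        if c.wm_anc is None:
            continue
        shade = 0.8 - 0.7 * i / max(n - 1, 1)
        ax.scatter(c.wm_di_combined, c.wm_anc, color=str(shade), edgecolor="k",
                   zorder=3, s=60)
        ax.annotate(str(c.cycle_index), (c.wm_di_combined, c.wm_anc),
                    textcoords="offset points", xytext=(5, 4), fontsize=8)
    if overall.wm_anc is not None:
        ax.scatter(overall.wm_di_combined, overall.wm_anc, color="red",
                   edgecolor="k", s=90, zorder=4, label="whole course")
        ax.legend(loc="best", fontsize=8)
    for y in rules.anc_target_range:
        ax.axhline(y, ls="--", lw=0.8, color="grey")
    ax.axvline(rules.di_threshold, ls=":", lw=0.8, color="grey")
    ax.set_xlabel("weighted mean combined dose intensity (%)")
    ax.set_ylabel("weighted mean ANC (10$^9$/L)")
    ax.set_title(f"{overall.patient_id}: cycle-specific summary measures")
    return _save(fig, Path(path))


def plot_cohort_scatter(
    summaries: Sequence[PatientSummary],
    rules: ProtocolRules,
    path: str | Path,
    groups: Optional[dict[str, str]] = None,
) -> Path:
    """Cohort treatment-intensity scatter with the desired region shaded.

    ``groups`` (patient_id -> label) colours points by group for
    pre/post-intervention comparisons.
    """
    fig, ax = plt.subplots(figsize=(6, 5))
    lo, hi = rules.anc_target_range
    xmax = max([s.wm_di_combined for s in summaries] + [120.0]) * 1.1
    ax.axhspan(lo, hi, xmin=0, facecolor="0.9", zorder=0)
    ax.fill_betweenx([lo, hi], rules.di_threshold, xmax, color="0.8", zorder=1)
    if groups:
        labels = sorted(set(groups.values()))
        colors = dict(zip(labels, ("tab:blue", "tab:orange")))
        for s in summaries:
            g = groups.get(s.patient_id, labels[0])
            ax.scatter(s.wm_di_combined, s.wm_anc, color=colors[g], zorder=3)
        for g, c in colors.items():
            ax.scatter([], [], color=c, label=g)
        ax.legend(fontsize=8)
    else:
        for s in summaries:
            if s.wm_anc is None:
                continue
            ax.scatter(s.wm_di_combined, s.wm_anc, color="k", zorder=3)
    for y in (lo, hi):
        ax.axhline(y, ls="--", lw=0.8, color="grey")
    ax.axvline(rules.di_threshold, ls="--", lw=0.8, color="grey")
    ax.set_xlim(0, xmax)
    ax.set_xlabel("weighted mean combined dose intensity (%)")
    ax.set_ylabel("weighted mean ANC (10$^9$/L)")
    ax.set_title(f"cohort treatment intensity (n={len(summaries)})")
    return _save(fig, Path(path))


def plot_cumulative_incidence(curve: pd.DataFrame, path: str | Path) -> Path:
    """Cumulative incidence (1 - KM survival) of first dose increase."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.step(curve["week"], 1.0 - curve["survival"], where="post", color="tab:blue")
    ax.axhline(0.5, ls=":", lw=0.8, color="grey")
    ax.set_xlabel("week of maintenance")
    ax.set_ylabel("cumulative incidence of first dose increase")
    ax.set_ylim(0, 1)
    return _save(fig, Path(path))
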