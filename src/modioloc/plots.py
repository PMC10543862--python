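"""Matplotlib figures for the method-comparison report.

All functions write a PNG and return its path; figure content is derived
solely from the paired-values tables and report objects so plots can be
re-rendered from saved run artifacts.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .agreement import AgreementReport
from .collocation import ShiftEstimate

_UNIT = {"EMD": "mm", "aDOI": "deg"}


def _save(fig, path) -> str:
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)


def scatter_plot(pairs: pd.DataFrame, parameter: str, path) -> str:
    """Candidate vs reference values with the line of equality."""
    u = _UNIT.get(parameter, "")
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(pairs["value_b"], pairs["value_a"], s=8, alpha=0.5)
    lims = [min(pairs["value_b"].min(), pairs["value_a"].min()),
            max(pairs["value_b"].max(), pairs["value_a"].max())]
    ax.plot(lims, lims, "k--", lw=1, label="equality")
    ax.set_xlabel(f"manual {parameter} ({u})")
    ax.set_ylabel(f"automatic {parameter} ({u})")
    ax.set_title(f"{parameter}: method scatter")
    ax.legend()
    fig.tight_layout()
    return _save(fig, path)


def _ba_panel(ax, pairs: pd.DataFrame, report: AgreementReport,
              parameter: str, title: str) -> None:
    u = _UNIT.get(parameter, "")
    ax.scatter(pairs["mean"], pairs["diff"], s=8, alpha=0.5)
    ax.axhline(report.bias, color="tab:blue", lw=1.2,
               label=f"bias {report.bias:+.3f}")
    for y in (report.loa_low, report.loa_high):
        ax.axhline(y, color="tab:red", lw=1, ls="--")
    ax.set_xlabel(f"mean of methods ({u})")
    ax.set_ylabel(f"difference auto - manual ({u})")
    ax.set_title(title)
    ax.legend(fontsize=8)


def bland_altman_plot(pairs_pre: pd.DataFrame, report_pre: AgreementReport,
                      pairs_post: pd.DataFrame | None,
                      report_post: AgreementReport | None,
                      parameter: str, path) -> str:
    """Bland-Altman panels, pre-collocation and (when available) post."""
    if pairs_post is not None and report_post is not None:
        fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
        _ba_panel(axes[0], pairs_pre, report_pre, parameter,
                  f"{parameter} pre-collocation")
        _ba_panel(axes[1], pairs_post, report_post, parameter,
                  f"{parameter} post-collocation")
    else:
        fig, ax = plt.subplots(figsize=(5, 4))
        _ba_panel(ax, pairs_pre, report_pre, parameter,
                  f"{parameter} pre-collocation")
    fig.tight_layout()
    return _save(fig, path)


def polar_means_plot(pairs_emd: pd.DataFrame, pairs_adoi: pd.DataFrame,
                     path) -> str:
    """Per-electrode mean (aDOI, EMD) of each method on polar axes."""
    fig = plt.figure(figsize=(5, 5))
    ax = fig.add_subplot(projection="polar")
    for col, label, marker in (("value_a", "automatic", "o"),
                               ("value_b", "manual", "s")):
        emd = pairs_emd.groupby("electrode")[col].mean()
        adoi = pairs_adoi.groupby("electrode")[col].mean()
        electrodes = emd.index
        ax.plot(np.deg2rad(adoi.loc[electrodes]), emd.loc[electrodes],
                marker=marker, ms=4, lw=1, label=label)
    ax.set_title("per-electrode mean EMD (mm) vs mean aDOI")
    ax.legend(loc="lower left", fontsize=8)
    fig.tight_layout()
    return _save(fig, path)


def shift_map_plot(shifts: Iterable[ShiftEstimate], path) -> str:
    """Per-array collocation shifts in the axis plane."""
    shifts = list(shifts)
    xs = [s.shift.shift_x for s in shifts]
    ys = [s.shift.shift_y for s in shifts]
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(xs, ys, s=14, alpha=0.7)
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("shift_x (mm)")
    ax.set_ylabel("shift_y (mm)")
    ax.set_title("per-array mid-modiolar axis shifts")
    ax.set_aspect("equal")
    fig.tight_layout()
    return _save(fig, path)
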