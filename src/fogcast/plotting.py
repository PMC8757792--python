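"""Plot helpers: sweep trends and real-time prediction timelines."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .evaluation import SweepResult
from .realtime import PredictionTimeline


def plot_sweep(result: SweepResult, il_fixed: int = 226, gl_fixed: int = 0):
    """Median F1 across subjects vs GL (left) and vs IL (right)."""
    fig, (ax_gl, ax_il) = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    for clf, sub in result.scores.groupby("classifier"):
        gl_med = (sub.query("IL == @il_fixed")
                  .groupby("GL")["F1"].median().loc[list(result.gl_grid)])
        il_med = (sub.query("GL == @gl_fixed")
                  .groupby("IL")["F1"].median().loc[list(result.il_grid)])
        ax_gl.plot(gl_med.index, gl_med.values, "o-", label=clf)
        ax_il.plot(il_med.index, il_med.values, "o-", label=clf)
    ax_gl.set_xlabel("GL (cs)")
    ax_gl.set_ylabel("median F1")
    ax_il.set_xlabel("IL (cs)")
    ax_gl.legend()
    fig.tight_layout()
    return fig


def plot_timeline(timeline: PredictionTimeline, trace=None):
    """Per-emission votes against ground truth; optionally the force on top."""
    n_rows = 2 if trace is not None else 1
    fig, axes = plt.subplots(n_rows, 1, figsize=(9, 2.5 * n_rows), sharex=True)
    axes = [axes] if n_rows == 1 else list(axes)
    frame = timeline.frame
    if trace is not None:
        axes[0].plot(trace.force, lw=0.5, color="0.4")
        axes[0].set_ylabel("force")
    ax = axes[-1]
    if timeline.has_ground_truth:
        ax.fill_between(frame["t_cs"], frame["gt"], step="mid",
                        alpha=0.3, label="ground truth")
    for rule, style in (("minority", "C1-"), ("majority", "C2--")):
        ax.step(frame["t_cs"], frame[rule], style, where="mid", label=rule)
    ax.set_xlabel("time (cs)")
    ax.set_ylabel("freeze")
    ax.legend(loc="upper right", fontsize="small")
    fig.tight_layout()
    return fig
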