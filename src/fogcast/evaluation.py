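"""Leave-one-subject-out evaluation and windowing-parameter sweeps.

The performance measure is the macro-averaged F1 score over the freeze
and no-freeze classes, summarised as the median across subjects.  A
model is evaluated on a subject only if it never saw that subject's
windows during training (leave-one-subject-out, LOSO), mimicking
deployment on a new patient.  Sweeps vary the input length IL (with
GL = 0) and the forecast horizon GL (at fixed IL) and report the
Spearman rank correlation of performance with GL — the quantitative
form of "the earlier the forecast, the harder it is".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classifiers import (
    EnsembleConfig,
    SingleClassError,
    _fit_member,
    predict_member,
)
from .stepsim import ForceTrace
from .windowing import WindowedDataset, WindowingParams, pool_datasets, window_trace

__all__ = [
    "ConfusionCounts",
    "SweepResult",
    "macro_f1",
    "confusion_counts",
    "loso_evaluate",
    "sweep",
    "gl_correlation",
    "compare_classifiers",
    "class_weight_sweep",
]

DEFAULT_IL_GRID = (28, 57, 113, 226, 339)
DEFAULT_GL_GRID = (0, 28, 57, 113)
IL_FIXED_FOR_GL_SWEEP = 226  # IL held constant while GL is varied
GL_FIXED_FOR_IL_SWEEP = 0


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with freeze (1) as the positive class."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion_counts(truth: np.ndarray, predicted: np.ndarray) -> ConfusionCounts:
    truth = np.asarray(truth, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if truth.shape != predicted.shape:
        raise ValueError("length mismatch")
    return ConfusionCounts(
        TP=int(((truth == 1) & (predicted == 1)).sum()),
        FP=int(((truth == 0) & (predicted == 1)).sum()),
        TN=int(((truth == 0) & (predicted == 0)).sum()),
        FN=int(((truth == 1) & (predicted == 0)).sum()),
    )


def _class_f1(tp: int, fp: int, fn: int, present: bool) -> float:
    # a class absent from both truth and prediction is perfectly handled
    if not present and fp == 0:
        return 1.0
    denom = 2 * tp + fp + fn
    return 2.0 * tp / denom if denom else 1.0


def macro_f1(truth: np.ndarray, predicted: np.ndarray) -> float:
    """Macro-averaged F1 over classes {0, 1}.

    The mean of the per-class F1 scores.  By convention a class absent
    from both the truth and the prediction contributes F1 = 1 (it was
    handled perfectly), so single-class inputs never yield NaN.
    """
    truth = np.asarray(truth, dtype=int)
    if truth.size == 0:
        raise ValueError("empty input")
    c = confusion_counts(truth, predicted)
    f1_pos = _class_f1(c.TP, c.FP, c.FN, present=bool(c.TP + c.FN))
    f1_neg = _class_f1(c.TN, c.FN, c.FP, present=bool(c.TN + c.FP))
    return 0.5 * (f1_pos + f1_neg)


# ---------------------------------------------------------------------------
# LOSO evaluation
# ---------------------------------------------------------------------------

def _window_cohort(
    traces: list[ForceTrace],
    labels: dict[str, np.ndarray] | None,
    params: WindowingParams,
) -> dict[str, WindowedDataset]:
    out = {}
    for trace in traces:
        lab = labels[trace.subject_id] if labels is not None else None
        ds = window_trace(trace, lab, params)
        if len(ds):
            out[trace.subject_id] = ds
    return out


def loso_evaluate(
    traces: list[ForceTrace],
    params: WindowingParams,
    *,
    labels: dict[str, np.ndarray] | None = None,
    classifiers=("nb", "rf", "nn"),
    config: EnsembleConfig | None = None,
) -> pd.DataFrame:
    """Leave-one-subject-out evaluation of the requested classifiers.

    For each held-out subject, each classifier is trained on the pooled
    windows of every *other* subject and scored on the held-out
    subject's windows.  Subjects whose trace yields no windows, or whose
    fold's training pool is single-class, are recorded as missing rather
    than zero.

    Returns a long-format frame with one row per (classifier, subject):
    columns ``classifier, subject, F1, TP, FP, TN, FN, n_test,
    train_subjects``.  ``train_subjects`` is the provenance of the fold
    (for leakage audits).
    """
    if labels is None and any(t.truth_labels is None for t in traces):
        raise ValueError("traces without truth_labels need an explicit labels dict")
    subjects = [t.subject_id for t in traces]
    if len(set(subjects)) < 2:
        raise ValueError("LOSO needs at least two distinct subjects")
    per_subject = _window_cohort(traces, labels, params)
    config = config or EnsembleConfig()

    rows = []
    for held_out in subjects:
        if held_out not in per_subject:
            continue  # no valid windows: missing, not zero
        train_ids = [s for s in per_subject if s != held_out]
        train = pool_datasets([per_subject[s] for s in train_ids])
        assert held_out not in set(train.subjects.tolist())
        test = per_subject[held_out]
        for name in classifiers:
            try:
                est = _fit_member(name, train.inputs, train.labels, config)
            except SingleClassError:
                continue
            pred = predict_member(name, est, test.inputs)
            c = confusion_counts(test.labels, pred)
            rows.append({
                "classifier": name,
                "subject": held_out,
                "F1": macro_f1(test.labels, pred),
                "TP": c.TP, "FP": c.FP, "TN": c.TN, "FN": c.FN,
                "n_test": len(test),
                "train_subjects": ",".join(sorted(train_ids)),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepResult:
    """Grid of per-subject F1 scores over (classifier, IL, GL).

    ``scores`` is long format: ``classifier, subject, IL, GL, F1`` plus
    confusion counts.  Summaries are computed over the per-subject
    scores actually present; missing cells are never imputed.
    """

    scores: pd.DataFrame
    il_grid: tuple
    gl_grid: tuple
    il_fixed: int = IL_FIXED_FOR_GL_SWEEP
    gl_fixed: int = GL_FIXED_FOR_IL_SWEEP

    def median_by(self, axis: str) -> pd.DataFrame:
        """Median and SD of F1 across subjects along one sweep axis.

        ``axis`` is ``"IL"`` (points at GL = gl_fixed) or ``"GL"``
        (points at IL = il_fixed).
        """
        sub = self._axis_scores(axis)
        g = sub.groupby(["classifier", axis])["F1"]
        return g.agg(median="median", sd="std", n="count").reset_index()

    def _axis_scores(self, axis: str) -> pd.DataFrame:
        if axis == "IL":
            return self.scores.query("GL == @self.gl_fixed")
        if axis == "GL":
            return self.scores.query("IL == @self.il_fixed")
        raise ValueError("axis must be 'IL' or 'GL'")

    def summary(self) -> str:
        lines = ["Windowing-parameter sweep", "=" * 40]
        for axis, fixed in (("IL", f"GL={self.gl_fixed}"),
                            ("GL", f"IL={self.il_fixed}")):
            sub = self._axis_scores(axis)
            if sub.empty:
                continue
            lines.append(f"median F1 across subjects by {axis} (at {fixed}):")
            table = sub.groupby(["classifier", axis])["F1"].median().unstack(axis)
            lines.append(table.round(3).to_string())
        return "\n".join(lines)


def sweep(
    traces: list[ForceTrace],
    *,
    il_grid=DEFAULT_IL_GRID,
    gl_grid=DEFAULT_GL_GRID,
    il_fixed: int = IL_FIXED_FOR_GL_SWEEP,
    gl_fixed: int = GL_FIXED_FOR_IL_SWEEP,
    tl: int = 1,
    ol: int = 28,
    labels: dict[str, np.ndarray] | None = None,
    classifiers=("nb", "rf", "nn"),
    config: EnsembleConfig | None = None,
) -> SweepResult:
    """Run the two windowing-parameter sweeps under LOSO.

    IL is varied over ``il_grid`` at ``GL = gl_fixed`` (default 0), and
    GL over ``gl_grid`` at ``IL = il_fixed`` (default 226 cs).  Each
    grid point is a full :func:`loso_evaluate` call; failures at a grid
    point propagate as missing cells.
    """
    if not il_grid and not gl_grid:
        raise ValueError("at least one of the grids must be non-empty")
    points = [(il, gl_fixed) for il in il_grid]
    points += [(il_fixed, gl) for gl in gl_grid if (il_fixed, gl) not in points]
    frames = []
    for il, gl in points:
        params = WindowingParams(IL=il, GL=gl, TL=tl, OL=ol)
        df = loso_evaluate(traces, params, labels=labels,
                           classifiers=classifiers, config=config)
        df["IL"] = il
        df["GL"] = gl
        frames.append(df)
    scores = pd.concat(frames, ignore_index=True)
    return SweepResult(scores=scores, il_grid=tuple(il_grid), gl_grid=tuple(gl_grid),
                       il_fixed=il_fixed, gl_fixed=gl_fixed)


def gl_correlation(
    result: SweepResult,
    classifier: str,
    *,
    il_fixed: int | None = None,
    per_subject: bool = False,
) -> tuple[float, float]:
    """Spearman rank correlation of F1 with the forecast horizon GL.

    By default correlates the (GL, median-across-subjects F1) pairs at
    the fixed IL of the GL sweep; with ``per_subject=True`` every
    (GL, per-subject F1) point enters instead.  Returns (rho, p-value);
    a constant series yields (nan, nan).
    """
    if il_fixed is None:
        il_fixed = result.il_fixed
    sub = result.scores.query("classifier == @classifier and IL == @il_fixed")
    sub = sub[sub["GL"].isin(result.gl_grid)]
    if per_subject:
        x, y = sub["GL"].to_numpy(float), sub["F1"].to_numpy(float)
    else:
        med = sub.groupby("GL")["F1"].median()
        x, y = med.index.to_numpy(float), med.to_numpy(float)
    if len(x) < 3:
        raise ValueError("need at least 3 GL points")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def compare_classifiers(*f1_groups) -> tuple[float, float]:
    """Kruskal-Wallis H test across per-subject F1 score groups.

    Each argument is the collection of per-subject F1 scores of one
    classifier.  Returns (H, p).  Identical groups give H ~ 0 (p ~ 1).
    """
    groups = [np.asarray(g, dtype=float) for g in f1_groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if np.ptp(np.concatenate(groups)) == 0:
        return 0.0, 1.0  # all observations tied
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def class_weight_sweep(
    traces: list[ForceTrace],
    *,
    weights=(1, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100),
    il: int = 113,
    gl: int = 0,
    tl: int = 1,
    ol: int = 28,
    labels: dict[str, np.ndarray] | None = None,
    config: EnsembleConfig | None = None,
) -> dict:
    """Robustness of the random forest to the freeze-class weight.

    Re-runs the LOSO evaluation of the RF at IL = 113, GL = 0 for each
    class weight (1 to 100 in steps of 10) and summarises robustness as
    the median over subjects of the per-subject SD of F1 across
    weights, alongside the median of the per-subject mean F1.
    """
    from dataclasses import replace

    config = config or EnsembleConfig()
    frames = []
    for w in weights:
        cfg = replace(config, rf_class_weight_true=float(w))
        df = loso_evaluate(traces, WindowingParams(IL=il, GL=gl, TL=tl, OL=ol),
                           labels=labels, classifiers=("rf",), config=cfg)
        df["weight"] = w
        frames.append(df)
    scores = pd.concat(frames, ignore_index=True)
    per_subject = scores.groupby("subject")["F1"]
    sd_across_weights = per_subject.std(ddof=0) if len(weights) == 1 else per_subject.std(ddof=1)
    mean_across_weights = per_subject.mean()
    return {
        "scores": scores,
        "median_sd": float(sd_across_weights.fillna(0.0).median()),
        "median_f1": float(mean_across_weights.median()),
        "weights": tuple(weights),
    }
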