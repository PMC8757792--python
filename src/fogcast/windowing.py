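"""Sliding-window transform turning labelled force traces into
forecast-classification datasets.

A window of total length ``WL = IL + GL + TL`` is slid along the trace
with an offset ``OL`` between consecutive starts.  The first ``IL``
samples form the classifier input; the label is read from the ``TL``
samples that follow a gap of ``GL`` samples.  ``GL`` is therefore the
forecast horizon: how far ahead of the end of the observed data the
freeze status is predicted.  All lengths are in centiseconds, which at
100 Hz equal samples.  Indexing is 0-based and half-open throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .stepsim import ForceTrace

__all__ = ["WindowingParams", "WindowedDataset", "window_trace", "pool_datasets"]


@dataclass(frozen=True)
class WindowingParams:
    """The four windowing lengths, in centiseconds (= samples at 100 Hz).

    Attributes
    ----------
    IL : input length, the number of force samples fed to the classifier.
    GL : gap length, the forecast horizon between input end and target.
    TL : target length; the window label is 1 iff any target sample is a
         freeze sample.  Default 1: predict the state of the single
         sample immediately after the gap.
    OL : offset between consecutive window starts.  Default 28 cs,
         approximately a quarter of the average step cycle, so that no
         step cycle is skipped between windows.
    """

    IL: int
    GL: int = 0
    TL: int = 1
    OL: int = 28

    def __post_init__(self) -> None:
        if self.IL < 1 or self.TL < 1 or self.OL < 1 or self.GL < 0:
            raise ValueError(
                "require IL >= 1, TL >= 1, OL >= 1, GL >= 0; got "
                f"IL={self.IL}, GL={self.GL}, TL={self.TL}, OL={self.OL}"
            )

    @property
    def WL(self) -> int:
        """Total window length IL + GL + TL."""
        return self.IL + self.GL + self.TL


@dataclass(frozen=True)
class WindowedDataset:
    """Matrix of input vectors with binary labels and provenance.

    ``inputs`` has one row of ``IL`` force samples per window; ``labels``
    is the {0,1} freeze flag extracted from each window's target region;
    ``subjects``/``starts`` record where each row came from.
    """

    inputs: np.ndarray  # (n_windows, IL) float
    labels: np.ndarray  # (n_windows,) int {0,1}
    subjects: np.ndarray  # (n_windows,) str
    starts: np.ndarray  # (n_windows,) int, window start sample
    params: WindowingParams

    def __post_init__(self) -> None:
        n = self.inputs.shape[0]
        if self.inputs.ndim != 2 or self.inputs.shape[1] != self.params.IL:
            raise ValueError("inputs must be (n, IL)")
        if not (self.labels.shape == self.subjects.shape == self.starts.shape == (n,)):
            raise ValueError("labels/subjects/starts must have one entry per row")
        if n and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return int(self.inputs.shape[0])

    def subset(self, subject_ids) -> "WindowedDataset":
        """Rows belonging to the given subject id(s)."""
        if isinstance(subject_ids, str):
            subject_ids = [subject_ids]
        mask = np.isin(self.subjects, list(subject_ids))
        return WindowedDataset(
            inputs=self.inputs[mask],
            labels=self.labels[mask],
            subjects=self.subjects[mask],
            starts=self.starts[mask],
            params=self.params,
        )


def _empty(params: WindowingParams) -> WindowedDataset:
    return WindowedDataset(
        inputs=np.empty((0, params.IL)),
        labels=np.empty(0, dtype=int),
        subjects=np.empty(0, dtype=object),
        starts=np.empty(0, dtype=int),
        params=params,
    )


def window_trace(
    trace: ForceTrace,
    labels: np.ndarray | None,
    params: WindowingParams,
    *,
    znorm: bool = False,
) -> WindowedDataset:
    """Window one labelled trace into a forecast-classification dataset.

    Windows start at 0, OL, 2*OL, ... while ``start + WL <= len(trace)``;
    the input of the window starting at ``s`` is ``force[s : s+IL)`` and
    its label is 1 iff any per-sample label in
    ``[s+IL+GL, s+IL+GL+TL)`` is 1.  Traces shorter than WL yield an
    empty dataset with a warning (trial lengths vary in practice).

    Parameters
    ----------
    labels : per-sample {0,1} labels aligned to the trace; if ``None``
        the trace's own ``truth_labels`` are used.
    znorm : if True, each input row is z-scored individually (mean 0,
        SD 1; constant rows become all zero).  Off by default: the raw
        kinetic values are the features.
    """
    if labels is None:
        labels = trace.truth_labels
    if labels is None:
        raise ValueError("no labels supplied and trace carries no truth_labels")
    labels = np.asarray(labels, dtype=int)
    force = trace.force
    if labels.shape != force.shape:
        raise ValueError("labels must align with the trace")

    n = force.size
    wl = params.WL
    if n < wl:
        warnings.warn(
            f"trace {trace.subject_id!r} shorter than WL ({n} < {wl}); "
            "no windows produced",
            stacklevel=2,
        )
        return _empty(params)

    n_windows = (n - wl) // params.OL + 1
    starts = np.arange(n_windows) * params.OL
    idx = starts[:, None] + np.arange(params.IL)[None, :]
    inputs = force[idx].astype(float)
    tstart = starts + params.IL + params.GL
    tidx = tstart[:, None] + np.arange(params.TL)[None, :]
    win_labels = (labels[tidx].max(axis=1) > 0).astype(int)

    if znorm:
        mu = inputs.mean(axis=1, keepdims=True)
        sd = inputs.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        inputs = (inputs - mu) / sd

    return WindowedDataset(
        inputs=inputs,
        labels=win_labels,
        subjects=np.full(n_windows, trace.subject_id, dtype=object),
        starts=starts,
        params=params,
    )


def pool_datasets(datasets) -> WindowedDataset:
    """Concatenate per-subject datasets sharing identical params."""
    datasets = list(datasets)
    if not datasets:
        raise ValueError("nothing to pool")
    params = datasets[0].params
    for d in datasets[1:]:
        if d.params != params:
            raise ValueError(f"mismatched windowing params: {d.params} != {params}")
    return WindowedDataset(
        inputs=np.concatenate([d.inputs for d in datasets], axis=0),
        labels=np.concatenate([d.labels for d in datasets]),
        subjects=np.concatenate([d.subjects for d in datasets]),
        starts=np.concatenate([d.starts for d in datasets]),
        params=params,
    )
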