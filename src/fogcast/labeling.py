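"""Automatic per-sample freeze labelling from the force trace alone.

Freezing suppresses the large body-weight transfer oscillation of
stepping, so a freeze shows up as a sustained collapse of the local
force oscillation amplitude.  The labeller measures amplitude as a
rolling peak-to-peak range, compares it against the trace's normal
stepping amplitude, and marks sufficiently long low-amplitude runs as
freezes.  It is a transparent stand-in validated against the
simulator's ground truth; every downstream stage also accepts
externally supplied labels so a different labeller (e.g. expert video
annotation) can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .stepsim import ForceTrace, episode_runs

__all__ = ["LabelerConfig", "label_trace", "label_agreement"]


@dataclass(frozen=True)
class LabelerConfig:
    """Amplitude-threshold labeller settings (lengths in centiseconds).

    ``baseline_window`` is the minimum amount of data required to
    estimate the normal stepping amplitude, taken as the 90th percentile
    of the rolling range over the whole trace (robust while freezing
    occupies well under 90% of the trial).  ``amplitude_threshold`` is
    the fraction of that baseline below which a sample is a freeze
    candidate; candidate runs shorter than ``min_freeze_duration`` are
    discarded.
    """

    baseline_window: int = 1000
    amplitude_threshold: float = 0.40
    min_freeze_duration: int = 100
    smoothing_window: int = 113
    baseline_percentile: float = 90.0

    def __post_init__(self) -> None:
        if not 0.0 < self.amplitude_threshold < 1.0:
            raise ValueError("amplitude_threshold must be in (0, 1)")
        if min(self.baseline_window, self.min_freeze_duration, self.smoothing_window) <= 0:
            raise ValueError("window lengths must be positive")


def rolling_amplitude(force: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling peak-to-peak range of the force signal."""
    force = np.asarray(force, dtype=float)
    return maximum_filter1d(force, window) - minimum_filter1d(force, window)


def label_trace(trace: ForceTrace, config: LabelerConfig = LabelerConfig()) -> np.ndarray:
    """Assign {0,1} freeze labels to every sample of a trace.

    A sample is labelled 1 iff it lies in a maximal run of samples whose
    rolling oscillation amplitude falls below
    ``amplitude_threshold x baseline`` and the run is at least
    ``min_freeze_duration`` long.
    """
    n = len(trace)
    if n < config.baseline_window:
        raise ValueError(
            f"trace has {n} samples; labelling requires at least "
            f"baseline_window = {config.baseline_window}"
        )
    amp = rolling_amplitude(trace.force, config.smoothing_window)
    baseline = np.percentile(amp, config.baseline_percentile)
    candidate = (amp < config.amplitude_threshold * baseline).astype(int)
    # enforce the minimum episode duration: drop short runs of 1s
    labels = candidate.copy()
    for start, length in episode_runs(candidate):
        if length < config.min_freeze_duration:
            labels[start:start + length] = 0
    return labels


def _episode_overlap_fraction(episode: tuple[int, int], labels: np.ndarray) -> float:
    start, length = episode
    return float(labels[start:start + length].sum()) / length


def label_agreement(predicted: np.ndarray, truth: np.ndarray) -> dict:
    """Agreement statistics between two per-sample label sequences.

    Returns per-sample ``accuracy`` plus episode-level ``recall`` and
    ``precision`` under a 50%-overlap rule: a truth episode counts as
    detected when at least half of its samples are predicted 1, and a
    predicted episode counts as correct when at least half of its
    samples are truth 1.  Episode-level statistics are 1.0 when the
    corresponding sequence contains no episodes.
    """
    predicted = np.asarray(predicted, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if predicted.shape != truth.shape:
        raise ValueError(
            f"length mismatch: predicted {predicted.size} vs truth {truth.size}"
        )
    accuracy = float((predicted == truth).mean())
    truth_eps = episode_runs(truth)
    pred_eps = episode_runs(predicted)
    recall = (
        float(np.mean([_episode_overlap_fraction(e, predicted) >= 0.5 for e in truth_eps]))
        if truth_eps else 1.0
    )
    precision = (
        float(np.mean([_episode_overlap_fraction(e, truth) >= 0.5 for e in pred_eps]))
        if pred_eps else 1.0
    )
    return {
        "accuracy": accuracy,
        "episode_recall": recall,
        "episode_precision": precision,
        "n_truth_episodes": len(truth_eps),
        "n_predicted_episodes": len(pred_eps),
    }
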