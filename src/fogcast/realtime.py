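"""Streaming real-time freeze prediction.

Force samples are consumed one at a time into a ring buffer of the
model's input length IL.  No prediction is possible until IL samples
have arrived; from then on a prediction is emitted every OL samples —
the deployment OL (10 cs in the real-time demonstration) may be finer
than the 28 cs used in training, giving higher temporal resolution from
the same model.  Each emission targets the sample GL centiseconds ahead
of the buffer's end, so the emission at target time ``t`` has seen only
samples before ``t - GL`` — the stream is causal by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifiers import MEMBERS, EnsembleForecasterResults, combine_votes
from .evaluation import confusion_counts
from .stepsim import ForceTrace
from .windowing import WindowingParams

__all__ = [
    "StreamState",
    "PredictionTimeline",
    "stream_predict",
    "timeline_error_rates",
]


@dataclass
class StreamState:
    """Ring buffer and emission bookkeeping for one force stream."""

    results: EnsembleForecasterResults
    params: WindowingParams
    _buffer: np.ndarray = field(init=False)
    _n_seen: int = field(init=False, default=0)
    _next_emit_start: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        if self.params.IL != self.results.il:
            raise ValueError(
                f"stream IL {self.params.IL} does not match the model's "
                f"training IL {self.results.il}"
            )
        self._buffer = np.empty(self.params.IL)

    def push(self, sample: float) -> dict | None:
        """Consume one sample; return an emission record or None.

        An emission is produced whenever the buffer holds the complete
        input window starting at the next scheduled start (starts are
        0, OL, 2*OL, ...).  The emission's target time is
        ``start + IL + GL``; the prediction uses only the buffered
        ``IL`` samples, i.e. nothing at or after ``target - GL``.
        """
        il = self.params.IL
        self._buffer[self._n_seen % il] = sample
        self._n_seen += 1
        if self._n_seen < il or self._n_seen != self._next_emit_start + il:
            return None
        start = self._next_emit_start
        self._next_emit_start += self.params.OL
        # unroll the ring buffer into chronological order
        pivot = self._n_seen % il
        window = np.concatenate((self._buffer[pivot:], self._buffer[:pivot]))
        votes = self.results.member_predictions(window[None, :])
        votes = {m: int(v[0]) for m, v in votes.items()}
        members = [votes[m] for m in MEMBERS]
        return {
            "start": start,
            "t_cs": start + il + self.params.GL,  # target sample index
            **{f"vote_{m}": votes[m] for m in MEMBERS},
            "minority": int(combine_votes(members, "minority")[0]),
            "majority": int(combine_votes(members, "majority")[0]),
        }


@dataclass(frozen=True)
class PredictionTimeline:
    """Per-emission votes, combined labels and ground truth.

    ``frame`` columns: ``t_cs`` (target sample, strictly increasing with
    spacing OL), ``vote_nb``, ``vote_rf``, ``vote_nn``, ``minority``,
    ``majority`` and optionally ``gt``.
    """

    frame: pd.DataFrame
    params: WindowingParams

    @property
    def has_ground_truth(self) -> bool:
        return "gt" in self.frame.columns

    def labels(self, rule: str) -> np.ndarray:
        if rule.endswith("_only"):
            return self.frame[f"vote_{rule[:-5]}"].to_numpy(int)
        return self.frame[rule].to_numpy(int)


def stream_predict(
    trace: ForceTrace,
    results: EnsembleForecasterResults,
    stream_params: WindowingParams,
    *,
    labels: np.ndarray | None = None,
) -> PredictionTimeline:
    """Run the streaming predictor over a full trace.

    Emissions target samples ``IL+GL, IL+GL+OL, ...`` while the target
    sample exists.  Ground truth, when per-sample labels are available,
    is the label at each emission's single target sample (TL = 1).
    """
    if stream_params.TL != 1:
        raise ValueError("streaming ground truth is defined for TL = 1")
    if len(trace) < stream_params.WL:
        raise ValueError("trace shorter than one full window")
    if labels is None:
        labels = trace.truth_labels
    state = StreamState(results=results, params=stream_params)
    records = []
    n = len(trace)
    for i, sample in enumerate(trace.force):
        emission = state.push(float(sample))
        if emission is not None:
            if emission["t_cs"] >= n:
                break  # target beyond the trace: no ground truth possible
            records.append(emission)
    frame = pd.DataFrame(records)
    if labels is not None and len(frame):
        frame["gt"] = np.asarray(labels, dtype=int)[frame["t_cs"].to_numpy()]
    return PredictionTimeline(frame=frame, params=stream_params)


def timeline_error_rates(timeline: PredictionTimeline) -> dict:
    """False-positive/negative rates and MFP/MFN per vote rule.

    For each of the minority and majority combinations: FP rate =
    FP/(FP+TN) and FN rate = FN/(FN+TP) over the emissions.  MFP and
    MFN are the mean false-positive and false-negative *counts* across
    the three individual members (they do not depend on the vote rule;
    they are reported alongside the combined-rule counts so the
    minority/majority trade-off can be read off directly).
    """
    if not timeline.has_ground_truth:
        raise ValueError("timeline carries no ground truth")
    gt = timeline.frame["gt"].to_numpy(int)
    out: dict = {}
    member_fp, member_fn = [], []
    for m in MEMBERS:
        c = confusion_counts(gt, timeline.frame[f"vote_{m}"].to_numpy(int))
        member_fp.append(c.FP)
        member_fn.append(c.FN)
        out[f"fp_count_{m}"] = c.FP
        out[f"fn_count_{m}"] = c.FN
    out["MFP"] = float(np.mean(member_fp))
    out["MFN"] = float(np.mean(member_fn))
    for rule in ("minority", "majority"):
        c = confusion_counts(gt, timeline.labels(rule))
        out[f"fp_rate_{rule}"] = c.FP / (c.FP + c.TN) if (c.FP + c.TN) else 0.0
        out[f"fn_rate_{rule}"] = c.FN / (c.FN + c.TP) if (c.FN + c.TP) else 0.0
        out[f"fp_count_{rule}"] = c.FP
        out[f"fn_count_{rule}"] = c.FN
    return out
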