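"""Synthetic stepping-in-place vertical ground-reaction-force simulator.

Generates per-subject vertical force traces at 100 Hz (1 sample = 1
centisecond) containing quasi-periodic stepping interrupted by freezing
episodes, together with per-sample ground-truth freeze labels.  The
generator is calibrated to a cohort of stepping-in-place trials from
people with Parkinson's disease and freezing of gait: a step cycle of
roughly 113 cs, about 3 freeze episodes per trial with a strongly
right-skewed duration distribution (mean ~12 s), and roughly a third of
all samples spent frozen.

During normal stepping the force oscillates about body weight.  Each
freeze onset is preceded by a configurable *degradation lead* over which
the oscillation amplitude decays linearly and the cadence slows; this
pre-freeze structure is what makes forecasting (rather than mere
detection) possible.  During a freeze the stepping oscillation is
replaced by low-amplitude trembling in a configurable frequency band
around body weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "SimConfig",
    "ForceTrace",
    "InfeasibleConfigError",
    "episode_schedule",
    "simulate_trace",
    "simulate_cohort",
]


class InfeasibleConfigError(ValueError):
    """Raised when the requested freeze episodes cannot fit the trial."""


@dataclass(frozen=True)
class ForceTrace:
    """One subject-trial's vertical force time series.

    Parameters
    ----------
    subject_id : str
        Identifier of the subject (used for leave-one-subject-out folds).
    sampling_rate : float
        Samples per second; 100 Hz makes one sample one centisecond.
    force : ndarray
        Vertical force, one value per sample (arbitrary units, lbs-scale).
    truth_labels : ndarray or None
        Optional per-sample {0,1} labels, 1 = freezing.
    """

    subject_id: str
    sampling_rate: float
    force: np.ndarray
    truth_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        force = np.asarray(self.force, dtype=float)
        if force.ndim != 1 or force.size < 1:
            raise ValueError("force must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(force)):
            raise ValueError("force values must be finite")
        object.__setattr__(self, "force", force)
        if self.truth_labels is not None:
            labels = np.asarray(self.truth_labels, dtype=int)
            if labels.shape != force.shape:
                raise ValueError(
                    f"labels length {labels.size} != force length {force.size}"
                )
            if not np.isin(labels, (0, 1)).all():
                raise ValueError("labels must be 0 or 1")
            object.__setattr__(self, "truth_labels", labels)

    def __len__(self) -> int:
        return int(self.force.size)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic cohort.

    All lengths and durations are in centiseconds unless noted.  The
    default ``trial_length`` of ``None`` derives a length consistent with
    the cohort statistics: with ``episodes_per_trial_mean`` episodes of
    ``episode_duration_mean`` seconds each occupying a fraction
    ``target_freeze_fraction`` of the trial, the implied trial length is
    ``episodes_per_trial_mean * episode_duration_mean / target_freeze_fraction``
    (~107 s at the defaults; trials ran for at least 90 s and continued
    until a freeze occurred, so the average trial exceeds 90 s).
    """

    n_subjects: int = 9
    trial_length: int | None = None  # cs; None -> derived from freeze fraction
    sampling_rate: float = 100.0  # Hz; 100 Hz == 1 sample per cs
    body_weight: float = 150.0  # lbs-scale
    body_weight_sd: float = 15.0  # between-subject spread
    cycle_length_mean: float = 113.0  # cs (4 x 28.4 cs quarter-cycle)
    cycle_length_sd: float = 30.0  # between-subject spread, cs
    step_amplitude: float = 0.35  # peak force swing, fraction of body weight
    step_amplitude_rel_sd: float = 0.12  # between-subject relative spread
    noise_sd: float = 3.0  # white measurement/physiological noise, lbs
    episodes_per_trial_mean: float = 3.0
    episodes_per_trial_sd: float = 1.6
    episode_duration_mean: float = 12.08  # seconds
    episode_duration_sd: float = 13.5  # seconds
    episode_duration_min: float = 1.0  # seconds, truncation floor
    target_freeze_fraction: float = 0.34
    degradation_lead: int = 150  # cs before each onset with decaying stepping
    cadence_slow_factor: float = 1.3  # cycle-length multiplier reached at onset
    tremble_freq_range: tuple[float, float] = (3.0, 8.0)  # Hz
    tremble_amplitude: float = 0.15  # fraction of the subject's step amplitude
    tremble_rel_sd: float = 0.10  # between-subject spread of trembling intensity
    drift_sd: float = 5.0  # stationary SD of slow postural baseline wander, lbs
    freeze_wander_sd: float = 15.0  # wander SD during freezes (weight shifting)
    drift_tau: float = 500.0  # wander relaxation time, cs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.trial_length is not None and self.trial_length < 1:
            raise ValueError("trial_length must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not 0.0 < self.target_freeze_fraction < 1.0:
            raise ValueError("target_freeze_fraction must be in (0, 1)")
        if self.degradation_lead < 0:
            raise ValueError("degradation_lead must be >= 0")
        for name in (
            "cycle_length_mean",
            "step_amplitude",
            "episode_duration_mean",
            "episode_duration_min",
            "episodes_per_trial_mean",
            "body_weight",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.tremble_freq_range
        if not 0 < lo <= hi:
            raise ValueError("tremble_freq_range must satisfy 0 < low <= high")

    @property
    def resolved_trial_length(self) -> int:
        """Trial length in samples, derived from the cohort statistics if unset."""
        if self.trial_length is not None:
            return int(self.trial_length)
        per_ep = self.episode_duration_mean * self.sampling_rate
        return int(round(self.episodes_per_trial_mean * per_ep / self.target_freeze_fraction))


def _duration_lognormal_params(mean_s: float, sd_s: float) -> tuple[float, float]:
    # moment-matched log-normal: mean/SD of the untruncated distribution
    sigma2 = math.log1p((sd_s / mean_s) ** 2)
    mu = math.log(mean_s) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def episode_schedule(
    config: SimConfig,
    rng: np.random.Generator,
    *,
    max_attempts: int = 200,
) -> list[tuple[int, int]]:
    """Draw a feasible freeze-episode schedule for one trial.

    Returns a list of ``(onset, duration)`` pairs in samples, sorted by
    onset.  Episode count is drawn from a rounded normal (clipped to at
    least one episode); durations from a moment-matched log-normal
    truncated below at ``episode_duration_min``.  Episodes are separated
    from each other and from the trace start by at least one step cycle
    plus the degradation lead, so every onset has room for its pre-freeze
    decay.

    Raises
    ------
    InfeasibleConfigError
        If no schedule fits the trial length after ``max_attempts``
        rejection-sampling rounds.
    """
    length = config.resolved_trial_length
    rate = config.sampling_rate
    min_gap = int(round(config.cycle_length_mean)) + config.degradation_lead
    mu, sigma = _duration_lognormal_params(
        config.episode_duration_mean, config.episode_duration_sd
    )
    min_dur = max(1, int(round(config.episode_duration_min * rate)))

    k = int(np.clip(round(rng.normal(config.episodes_per_trial_mean,
                                     config.episodes_per_trial_sd)), 1, None))
    for _ in range(max_attempts):
        durations = np.exp(rng.normal(mu, sigma, size=k))
        durations = np.maximum((durations * rate).round().astype(int), min_dur)
        # slack left after reserving the episodes and the mandatory gaps
        slack = length - k * min_gap - int(durations.sum())
        if slack < 0:
            continue
        # spread the slack over the k+1 inter-episode spaces at random
        cuts = np.sort(rng.integers(0, slack + 1, size=k))
        extra = np.diff(np.concatenate(([0], cuts)))
        onsets = []
        pos = 0
        for i in range(k):
            pos += min_gap + int(extra[i])
            onsets.append(pos)
            pos += int(durations[i])
        return list(zip(onsets, durations.tolist()))
    raise InfeasibleConfigError(
        f"could not fit {k} episodes (min gap {min_gap} cs) into "
        f"{length} cs after {max_attempts} attempts"
    )


def _subject_params(config: SimConfig, rng: np.random.Generator) -> dict:
    """Per-subject draws: body weight, step cycle, step amplitude."""
    weight = max(50.0, rng.normal(config.body_weight, config.body_weight_sd))
    cycle = float(np.clip(rng.normal(config.cycle_length_mean, config.cycle_length_sd),
                          40.0, None))
    amp = config.step_amplitude * float(
        np.clip(rng.normal(1.0, config.step_amplitude_rel_sd), 0.3, 1.7)
    )
    tremble = config.tremble_amplitude * float(
        np.clip(rng.normal(1.0, config.tremble_rel_sd), 0.15, 1.9)
    )
    return {"weight": weight, "cycle": cycle, "amplitude": amp, "tremble": tremble}


def simulate_trace(
    config: SimConfig,
    subject_id: str,
    rng: np.random.Generator,
) -> ForceTrace:
    """Simulate one labelled trial for one subject."""
    n = config.resolved_trial_length
    sp = _subject_params(config, rng)
    schedule = episode_schedule(config, rng)

    labels = np.zeros(n, dtype=int)
    for onset, dur in schedule:
        labels[onset:min(onset + dur, n)] = 1

    # per-sample amplitude envelope (fraction of subject amplitude) and
    # per-sample instantaneous cycle length; freeze samples carry no stepping
    envelope = np.ones(n)
    cycle = np.full(n, sp["cycle"])
    lead = config.degradation_lead
    for onset, dur in schedule:
        end = min(onset + dur, n)
        envelope[onset:end] = 0.0
        if lead > 0:
            a = max(0, onset - lead)
            ramp = np.linspace(1.0, 0.0, onset - a, endpoint=False)
            envelope[a:onset] = np.minimum(envelope[a:onset], ramp)
            cyc_ramp = sp["cycle"] * np.linspace(1.0, config.cadence_slow_factor,
                                                 onset - a, endpoint=False)
            cycle[a:onset] = cyc_ramp

    # slow per-step cadence jitter, applied as a smooth per-sample wobble
    jitter = rng.normal(0.0, 0.03, size=n // max(int(sp["cycle"]), 1) + 2)
    per_sample_jitter = np.repeat(jitter, int(sp["cycle"]))[:n]
    if per_sample_jitter.size < n:
        per_sample_jitter = np.pad(per_sample_jitter, (0, n - per_sample_jitter.size))
    cycle = cycle * (1.0 + per_sample_jitter)

    phase0 = rng.uniform(0.0, 2.0 * math.pi)
    phase = phase0 + 2.0 * math.pi * np.cumsum(1.0 / cycle)
    stepping = envelope * sp["amplitude"] * np.sin(phase)

    force = sp["weight"] * (1.0 + stepping)

    # slow postural baseline wander: mean-reverting (OU) process whose
    # stationary SD is larger inside freezes, where subjects shift their
    # weight gradually instead of stepping
    if config.drift_sd > 0 or config.freeze_wander_sd > 0:
        sd_t = np.where(labels == 1, config.freeze_wander_sd, config.drift_sd)
        decay = 1.0 - 1.0 / config.drift_tau
        step_scale = sd_t * math.sqrt(2.0 / config.drift_tau)
        shocks = rng.normal(0.0, 1.0, size=n) * step_scale
        wander = lfilter([1.0], [1.0, -decay], shocks)
        force = force + wander

    # trembling component inside each freeze episode
    if config.tremble_amplitude > 0 and sp["tremble"] > 0:
        t = np.arange(n) / config.sampling_rate
        for onset, dur in schedule:
            end = min(onset + dur, n)
            freq = rng.uniform(*config.tremble_freq_range)
            tphase = rng.uniform(0.0, 2.0 * math.pi)
            tremble = (sp["tremble"] * sp["amplitude"] * sp["weight"]
                       * np.sin(2.0 * math.pi * freq * t[onset:end] + tphase))
            force[onset:end] += tremble

    if config.noise_sd > 0:
        force = force + rng.normal(0.0, config.noise_sd, size=n)

    return ForceTrace(
        subject_id=subject_id,
        sampling_rate=config.sampling_rate,
        force=force,
        truth_labels=labels,
    )


def simulate_cohort(config: SimConfig) -> list[ForceTrace]:
    """Simulate one labelled trial per subject.

    Deterministic given ``config.seed``: the cohort random stream is a
    single :class:`numpy.random.Generator` seeded from the config.
    """
    rng = np.random.default_rng(config.seed)
    return [
        simulate_trace(config, subject_id=f"S{i:02d}", rng=rng)
        for i in range(config.n_subjects)
    ]


def episode_runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Run-length encode the freeze episodes of a {0,1} label sequence.

    Returns ``(start, length)`` pairs of the maximal runs of 1s.  This is
    the independent counting routine used to validate episode statistics.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        return []
    edges = np.flatnonzero(np.diff(labels) != 0) + 1
    bounds = np.concatenate(([0], edges, [labels.size]))
    return [
        (int(bounds[i]), int(bounds[i + 1] - bounds[i]))
        for i in range(len(bounds) - 1)
        if labels[bounds[i]] == 1
    ]
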