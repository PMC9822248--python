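"""Synthetic voltage-clamp current traces with ground-truth events.

Four trace kinds cover the evoked and spontaneous protocols the metrics
module analyzes: paired-pulse stimulation, hypertonic-sucrose application,
miniature-event recordings, and stimulus trains (50 stimuli at 10 Hz by
default).  PSC waveforms are biexponential with unit-peak normalization, so
an inserted amplitude is exactly the waveform's peak deflection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ParameterError
from ..metrics import biexp_template
from ..trace import SweepTrace

__all__ = [
    "TraceGroundTruth",
    "simulate_trace",
    "simulate_evoked_pair",
    "simulate_sucrose_step",
    "simulate_minis",
    "simulate_train",
]


@dataclass(frozen=True)
class TraceGroundTruth:
    """Everything that was inserted into a synthetic trace.

    ``events`` lists (time s, amplitude pA) for every inserted PSC;
    ``charge`` (pC) is filled for sucrose steps, ``ppr`` for evoked pairs.
    """

    events: tuple[tuple[float, float], ...] = field(default_factory=tuple)
    ppr: float | None = None
    charge: float | None = None     # pC, over the full plateau
    noise_sd: float = 0.0


def _add_waveform(samples: np.ndarray, start_idx: int, wave: np.ndarray) -> None:
    end = min(samples.size, start_idx + wave.size)
    if end > start_idx >= 0:
        samples[start_idx:end] += wave[: end - start_idx]


def _add_artifact(samples: np.ndarray, idx: int, amp: float, fs: float) -> None:
    # biphasic stimulus artifact, ~0.4 ms, inside the default blanking window
    n = max(2, int(round(0.0004 * fs)))
    half = n // 2
    samples[idx:idx + half] += amp
    samples[idx + half:idx + n] -= amp


def simulate_evoked_pair(a1: float = 100.0, a2: float = 150.0,
                         interval_ms: float = 50.0, *,
                         sampling_rate: float = 5000.0,
                         latency_ms: float = 4.0,
                         tau_rise_ms: float = 0.5, tau_decay_ms: float = 5.0,
                         artifact_pa: float = 0.0, noise_sd: float = 0.0,
                         polarity: str = "inward",
                         pre_s: float = 0.05, post_s: float = 0.1,
                         seed: int = 0) -> tuple[SweepTrace, TraceGroundTruth]:
    """Two evoked PSCs of amplitudes ``a1`` and ``a2`` (pA, magnitudes)."""
    if min(a1, a2) < 0 or interval_ms <= 0:
        raise ParameterError("amplitudes must be >= 0 and interval > 0")
    rng = np.random.default_rng(seed)
    t1, t2 = pre_s, pre_s + interval_ms / 1000.0
    n = int(round((t2 + post_s) * sampling_rate))
    sign = -1.0 if polarity == "inward" else 1.0
    x = np.zeros(n)
    w = biexp_template(tau_rise_ms, tau_decay_ms, sampling_rate)
    for t, a in ((t1, a1), (t2, a2)):
        onset = int(round((t + latency_ms / 1000.0) * sampling_rate))
        _add_waveform(x, onset, sign * a * w)
        if artifact_pa:
            _add_artifact(x, int(round(t * sampling_rate)), artifact_pa, sampling_rate)
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, size=n)
    trace = SweepTrace(samples=x, sampling_rate=sampling_rate,
                       stimulus_times=(t1, t2), polarity=polarity)
    truth = TraceGroundTruth(events=((t1, a1), (t2, a2)),
                             ppr=(a2 / a1 if a1 > 0 else None), noise_sd=noise_sd)
    return trace, truth


def simulate_sucrose_step(plateau_pa: float = 100.0, *, onset_s: float = 1.0,
                          plateau_s: float = 10.0, post_s: float = 1.0,
                          sampling_rate: float = 5000.0, noise_sd: float = 0.0,
                          polarity: str = "inward",
                          seed: int = 0) -> tuple[SweepTrace, TraceGroundTruth]:
    """A sustained sucrose-evoked current plateau of known charge.

    Ground-truth charge (pC) is the numerically integrated noise-free
    response, |plateau| x duration for the rectangular default.
    """
    if plateau_pa < 0 or plateau_s <= 0:
        raise ParameterError("plateau magnitude >= 0 and duration > 0 required")
    rng = np.random.default_rng(seed)
    n = int(round((onset_s + plateau_s + post_s) * sampling_rate))
    sign = -1.0 if polarity == "inward" else 1.0
    clean = np.zeros(n)
    i0 = int(round(onset_s * sampling_rate))
    i1 = int(round((onset_s + plateau_s) * sampling_rate))
    clean[i0:i1] = sign * plateau_pa
    charge = float(np.trapezoid(np.abs(clean), dx=1.0 / sampling_rate))
    x = clean + rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else clean.copy()
    trace = SweepTrace(samples=x, sampling_rate=sampling_rate,
                       stimulus_times=(onset_s,), polarity=polarity)
    return trace, TraceGroundTruth(charge=charge, noise_sd=noise_sd)


def simulate_minis(rate_hz: float = 0.5, *, duration_s: float = 102.0,
                   amplitude_pa: float = 30.0, amplitude_cv: float = 0.0,
                   tau_rise_ms: float = 0.5, tau_decay_ms: float = 4.0,
                   sampling_rate: float = 5000.0, noise_sd: float = 2.0,
                   polarity: str = "inward", event_times: tuple[float, ...] | None = None,
                   min_separation_s: float = 0.05,
                   seed: int = 0) -> tuple[SweepTrace, TraceGroundTruth]:
    """Baseline trace with template-shaped miniature events.

    Events occur at ``event_times`` if given, otherwise as a Poisson process
    of rate ``rate_hz`` (thinned to a minimum separation so ground-truth
    events stay resolvable).  ``rate_hz = 0`` gives baseline plus noise only.
    """
    if rate_hz < 0 or duration_s <= 0:
        raise ParameterError("rate >= 0 and duration > 0 required")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sampling_rate))
    sign = -1.0 if polarity == "inward" else 1.0
    x = np.zeros(n)
    w = biexp_template(tau_rise_ms, tau_decay_ms, sampling_rate)
    margin = w.size / sampling_rate
    if event_times is None:
        n_events = rng.poisson(rate_hz * duration_s)
        times = np.sort(rng.uniform(0.0, duration_s - margin, size=n_events))
        keep = []
        last = -np.inf
        for t in times:
            if t - last >= min_separation_s:
                keep.append(t)
                last = t
        times = np.asarray(keep)
    else:
        times = np.asarray(event_times, dtype=float)
    events = []
    for t in times:
        a = amplitude_pa
        if amplitude_cv > 0:
            a = max(0.0, rng.normal(amplitude_pa, amplitude_cv * amplitude_pa))
        _add_waveform(x, int(round(t * sampling_rate)), sign * a * w)
        events.append((float(t), float(a)))
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, size=n)
    trace = SweepTrace(samples=x, sampling_rate=sampling_rate, polarity=polarity)
    return trace, TraceGroundTruth(events=tuple(events), noise_sd=noise_sd)


def simulate_train(n_stimuli: int = 50, rate: float = 10.0, *,
                   first_amplitude: float = 100.0, depression_ratio: float = 0.9,
                   amplitudes: np.ndarray | None = None,
                   sampling_rate: float = 5000.0, latency_ms: float = 4.0,
                   tau_rise_ms: float = 0.5, tau_decay_ms: float = 5.0,
                   artifact_pa: float = 0.0, noise_sd: float = 0.0,
                   polarity: str = "inward", pre_s: float = 0.1,
                   seed: int = 0) -> tuple[SweepTrace, TraceGroundTruth]:
    """A stimulus train (default 50 stimuli at 10 Hz) with known amplitudes.

    Amplitudes follow a geometric depression ``first_amplitude *
    depression_ratio**i`` unless given explicitly.
    """
    if n_stimuli < 1 or rate <= 0:
        raise ParameterError("need n_stimuli >= 1 and rate > 0")
    rng = np.random.default_rng(seed)
    if amplitudes is None:
        amplitudes = first_amplitude * depression_ratio ** np.arange(n_stimuli)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.size != n_stimuli:
        raise ParameterError("amplitudes length must equal n_stimuli")
    isi = 1.0 / rate
    stim_times = tuple(pre_s + i * isi for i in range(n_stimuli))
    n = int(round((stim_times[-1] + isi) * sampling_rate))
    sign = -1.0 if polarity == "inward" else 1.0
    x = np.zeros(n)
    w = biexp_template(tau_rise_ms, tau_decay_ms, sampling_rate)
    for t, a in zip(stim_times, amplitudes):
        _add_waveform(x, int(round((t + latency_ms / 1000.0) * sampling_rate)), sign * a * w)
        if artifact_pa:
            _add_artifact(x, int(round(t * sampling_rate)), artifact_pa, sampling_rate)
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, size=n)
    trace = SweepTrace(samples=x, sampling_rate=sampling_rate,
                       stimulus_times=stim_times, polarity=polarity)
    truth = TraceGroundTruth(events=tuple(zip(stim_times, map(float, amplitudes))),
                             noise_sd=noise_sd)
    return trace, truth


_KINDS = {
    "evoked_pair": simulate_evoked_pair,
    "sucrose_step": simulate_sucrose_step,
    "minis": simulate_minis,
    "train": simulate_train,
}


def simulate_trace(kind: str, seed: int = 0, **shape_params):
    """Dispatch to one of the trace generators by kind.

    ``kind`` is one of ``evoked_pair``, ``sucrose_step``, ``minis``,
    ``train``; remaining keyword arguments are forwarded.
    """
    if kind not in _KINDS:
        raise ParameterError(f"unknown trace kind {kind!r}; choose from {sorted(_KINDS)}")
    return _KINDS[kind](seed=seed, **shape_params)
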