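"""Leak point pressure and EMG/ENG firing-rate analysis.

Extracts per-trial urodynamic and neural metrics and aggregates them to
per-animal means:

- LPP: peak bladder pressure at the leak event minus mean baseline pressure
  (cm H2O).
- Firing rate and amplitude of 1-s EMG/ENG segments at baseline and during
  stimulation (peak pressure for EUS EMG, genital brushing for pudendal
  ENG), with outcomes reported as stimulated-minus-baseline differences.

Spike detection is threshold-based on the (already band-limited) voltage:
the noise level is estimated on a quiet reference window — robustly via the
median absolute deviation by default, since reference windows contain
baseline spikes — and spikes are upward crossings of
``center + threshold_sd * spread`` with a 1 ms refractory period. Per-spike
amplitude is the local peak-to-peak within +/-1 ms of the crossing. Traces
flagged ``raw=True`` are band-pass filtered (3 Hz - 3 kHz) first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .synthetic import NeuroTrace, PressureTrace

__all__ = [
    "SegmentMetrics",
    "AnimalOutcome",
    "compute_lpp",
    "detect_spikes",
    "segment_metrics",
    "delta_metrics",
    "analyze_lpp_trial",
    "analyze_eng_trial",
    "animal_outcome",
    "outcomes_to_frame",
]

BANDPASS_HZ = (3.0, 3000.0)
DEFAULT_THRESHOLD_SD = 4.5
REFRACTORY_S = 0.001
# peak-to-peak window around a threshold crossing: the crossing sits at the
# onset of a ~2 ms biphasic wave, so look 1 ms back and 2 ms forward
AMPLITUDE_PRE_S = 0.001
AMPLITUDE_POST_S = 0.002


@dataclass(frozen=True)
class SegmentMetrics:
    """Firing rate (Hz) and mean spike amplitude (uV) of one 1-s segment."""

    firing_rate: float
    amplitude: float
    duration: float = 1.0

    def __post_init__(self) -> None:
        if self.firing_rate < 0:
            raise ValueError("firing rate must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


@dataclass
class AnimalOutcome:
    """Per-animal functional outcomes, trial-averaged.

    Missing metrics (no usable trials) are NaN, never zero.
    """

    animal_id: str
    group: str
    lpp: float = math.nan
    d_emg_rate: float = math.nan
    d_emg_amp: float = math.nan
    d_eng_rate: float = math.nan
    d_eng_amp: float = math.nan


def compute_lpp(trace: PressureTrace, peak_halfwidth: float = 0.25) -> float:
    """Leak point pressure: peak pressure minus mean baseline pressure.

    The peak is the maximum within ``peak_halfwidth`` seconds of the leak
    marker; the baseline is the mean over the annotated baseline window,
    which must precede the marker.
    """
    b0, b1 = trace.baseline_window
    if trace.peak_time <= b1:
        raise ValueError("leak marker must lie after the baseline window")
    t = trace.time
    base = trace.pressure[(t >= b0) & (t <= b1)]
    if len(base) == 0:
        raise ValueError("baseline window contains no samples")
    near = trace.pressure[np.abs(t - trace.peak_time) <= peak_halfwidth]
    if len(near) == 0:
        raise ValueError("no samples near the leak marker")
    return float(np.max(near) - np.mean(base))


def _bandpass(voltage: np.ndarray, sample_rate: float) -> np.ndarray:
    lo, hi = BANDPASS_HZ
    sos = butter(4, [lo, min(hi, 0.45 * sample_rate)], btype="bandpass", fs=sample_rate, output="sos")
    return sosfiltfilt(sos, voltage)


def _noise_stats(reference: np.ndarray, estimator: str) -> Tuple[float, float]:
    if estimator == "mad":
        center = float(np.median(reference))
        spread = float(np.median(np.abs(reference - center)) / 0.6744897501960817)
    elif estimator == "std":
        center = float(np.mean(reference))
        spread = float(np.std(reference))
    else:
        raise ValueError(f"unknown noise estimator {estimator!r}")
    if spread == 0.0:
        raise ValueError("zero-variance reference window: cannot estimate a noise threshold")
    return center, spread


def detect_spikes(
    trace: NeuroTrace,
    window: Tuple[float, float],
    reference_window: Tuple[float, float] | None = None,
    threshold_sd: float = DEFAULT_THRESHOLD_SD,
    noise_estimator: str = "mad",
) -> Tuple[np.ndarray, np.ndarray]:
    """Detect spikes inside ``window``; returns (times, peak-to-peak amps).

    The detection threshold is noise-relative (center + threshold_sd *
    spread, estimated on ``reference_window``, defaulting to the trace's
    baseline window), so detection counts are invariant to a global gain
    applied to the voltage.
    """
    v = trace.voltage
    if trace.raw:
        v = _bandpass(v, trace.sample_rate)
    t = trace.time
    ref0, ref1 = reference_window if reference_window is not None else trace.baseline_window
    reference = v[(t >= ref0) & (t <= ref1)]
    if len(reference) < 2:
        raise ValueError("reference window contains fewer than 2 samples")
    center, spread = _noise_stats(reference, noise_estimator)
    threshold = center + threshold_sd * spread

    w0, w1 = window
    idx = np.flatnonzero((t >= w0) & (t <= w1))
    if len(idx) < 2:
        raise ValueError("analysis window contains fewer than 2 samples")
    seg = v[idx]
    crossings = np.flatnonzero((seg[:-1] < threshold) & (seg[1:] >= threshold)) + 1

    pre_n = int(round(AMPLITUDE_PRE_S * trace.sample_rate))
    post_n = int(round(AMPLITUDE_POST_S * trace.sample_rate))
    times: List[float] = []
    amps: List[float] = []
    last = -np.inf
    for c in crossings:
        gi = idx[c]  # index into the full trace
        if t[gi] - last < REFRACTORY_S:
            continue
        last = t[gi]
        lo = max(gi - pre_n, 0)
        hi = min(gi + post_n + 1, len(v))
        amps.append(float(np.max(v[lo:hi]) - np.min(v[lo:hi])))
        times.append(float(t[gi]))
    return np.asarray(times), np.asarray(amps)


def segment_metrics(
    spike_times: np.ndarray, amplitudes: np.ndarray, duration: float = 1.0
) -> SegmentMetrics:
    """Rate = count/duration; amplitude = mean peak-to-peak (0 if no spikes)."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n = len(spike_times)
    amp = float(np.mean(amplitudes)) if n else 0.0
    return SegmentMetrics(firing_rate=n / duration, amplitude=amp, duration=duration)


def delta_metrics(
    baseline: SegmentMetrics, stim: SegmentMetrics
) -> Tuple[float, float]:
    """(stim - baseline) differences of firing rate (Hz) and amplitude (uV)."""
    return stim.firing_rate - baseline.firing_rate, stim.amplitude - baseline.amplitude


def _trial_deltas(
    etrace: NeuroTrace, threshold_sd: float, noise_estimator: str
) -> Tuple[float, float]:
    base = segment_metrics(
        *detect_spikes(etrace, etrace.baseline_window, threshold_sd=threshold_sd,
                       noise_estimator=noise_estimator),
        duration=etrace.baseline_window[1] - etrace.baseline_window[0],
    )
    stim = segment_metrics(
        *detect_spikes(etrace, etrace.stim_window, threshold_sd=threshold_sd,
                       noise_estimator=noise_estimator),
        duration=etrace.stim_window[1] - etrace.stim_window[0],
    )
    return delta_metrics(base, stim)


def analyze_lpp_trial(
    ptrace: PressureTrace,
    etrace: NeuroTrace,
    threshold_sd: float = DEFAULT_THRESHOLD_SD,
    noise_estimator: str = "mad",
) -> Tuple[float, float, float]:
    """One LPP trial -> (lpp, d_emg_rate, d_emg_amp)."""
    lpp = compute_lpp(ptrace)
    d_rate, d_amp = _trial_deltas(etrace, threshold_sd, noise_estimator)
    return lpp, d_rate, d_amp


def analyze_eng_trial(
    etrace: NeuroTrace,
    threshold_sd: float = DEFAULT_THRESHOLD_SD,
    noise_estimator: str = "mad",
) -> Tuple[float, float]:
    """One ENG trial -> (d_eng_rate, d_eng_amp)."""
    return _trial_deltas(etrace, threshold_sd, noise_estimator)


def animal_outcome(
    animal_id: str,
    group: str,
    lpp_trials: Sequence[float] = (),
    emg_deltas: Sequence[Tuple[float, float]] = (),
    eng_deltas: Sequence[Tuple[float, float]] = (),
) -> AnimalOutcome:
    """Aggregate per-trial metrics to per-animal arithmetic means.

    A metric with no trials is recorded as NaN (missing, not zero).
    """
    out = AnimalOutcome(animal_id=animal_id, group=group)
    if lpp_trials:
        out.lpp = float(np.mean(lpp_trials))
    if emg_deltas:
        out.d_emg_rate = float(np.mean([d[0] for d in emg_deltas]))
        out.d_emg_amp = float(np.mean([d[1] for d in emg_deltas]))
    if eng_deltas:
        out.d_eng_rate = float(np.mean([d[0] for d in eng_deltas]))
        out.d_eng_amp = float(np.mean([d[1] for d in eng_deltas]))
    return out


def outcomes_to_frame(outcomes: Sequence[AnimalOutcome]) -> pd.DataFrame:
    """Tidy long table: animal_id, group, metric, value (NaN = missing)."""
    rows = []
    for o in outcomes:
        for metric in ("lpp", "d_emg_rate", "d_emg_amp", "d_eng_rate", "d_eng_amp"):
            rows.append(
                {
                    "animal_id": o.animal_id,
                    "group": o.group,
                    "metric": metric,
                    "value": getattr(o, metric),
                }
            )
    return pd.DataFrame(rows)
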