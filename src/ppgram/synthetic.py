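"""Synthetic wrist-PPG generation and ground-truth regression fixtures.

No public recordings accompany the monitoring problem this package targets,
so every other module is exercised against simulated signals.  The simulator
emulates the phenomenology of a conscious, free-moving wearer of a wrist
PPG band:

* quasi-periodic cardiac pulses — beat onsets drawn with jittered intervals
  (mean ``60/hr_bpm`` s, sd ``hrv_sd``, truncated positive);
* a two-Gaussian pulse template per beat (systolic wave plus a dicrotic
  wave rendered as a shoulder on the falling edge), parameterized in
  fractions of the beat interval so morphology scales with beat length;
* sinusoidal baseline wander (respiratory-band drift);
* additive white sensor noise;
* sporadic motion artifacts — Poisson-timed high-amplitude damped
  oscillatory transients.

The recording starts mid-cardiac-cycle (first beat onset half an interval
before t = 0), as a band switched on at an arbitrary moment would: a 5-minute
artifact-free 80 bpm record therefore contains 400 interior troughs and
segments into 399 complete trough-to-trough waveforms.

Independent random streams drive beats, noise, wander phase, and artifacts,
so switching artifacts off perturbs nothing else; everything is
seed-deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.polynomial import chebyshev as _cheb

from .datasets import Phase, WaveformDataset
from .segmentation import Waveform
from .signal_io import PPGRecord, ValidationError, Wrist

logger = logging.getLogger(__name__)

__all__ = ["PulseShape", "SimulationParams", "simulate_ppg", "simulate_run",
           "make_polynomial_dataset"]

#: Empatica E4 BVP channel sampling rate (Hz); the device-documented default.
DEFAULT_SAMPLE_RATE = 64.0


@dataclass(frozen=True)
class PulseShape:
    """Two-Gaussian pulse template, in fractions of the beat interval.

    The second (dicrotic/diastolic) wave is placed and widened so that it
    forms a shoulder on the systolic falling edge rather than a separate
    local extremum: each beat then contains exactly one trough, which the
    segmentation stage relies on.
    """

    systolic_amp: float = 1.0
    systolic_center: float = 0.18
    systolic_width: float = 0.16
    dicrotic_amp: float = 0.40
    dicrotic_center: float = 0.55
    dicrotic_width: float = 0.22


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the PPG simulator.

    duration : s — length of the generated record.
    hr_bpm : mean heart rate (30 < hr < 220); 80 bpm is the nominal rate.
    hrv_sd : s — beat-interval jitter (sd of the truncated normal).
    noise_sd : BVP units — additive white noise sd.
    baseline_amp / baseline_freq : BVP units / Hz — wander sinusoid
        (respiratory band; phase drawn per seed).
    artifact_rate : expected motion artifacts per minute.
    artifact_amp : artifact transient scale, BVP units.
    seed : master RNG seed; child streams for beats / noise / wander /
        artifacts are spawned from it.
    """

    duration: float = 300.0
    hr_bpm: float = 80.0
    hrv_sd: float = 0.03
    pulse_shape: PulseShape = field(default_factory=PulseShape)
    noise_sd: float = 0.02
    baseline_amp: float = 0.25
    baseline_freq: float = 0.25
    artifact_rate: float = 2.0
    artifact_amp: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if not self.duration > 0:
            raise ValidationError(f"duration must be positive, got {self.duration}")
        if not (30.0 < self.hr_bpm < 220.0):
            raise ValidationError(f"hr_bpm must lie in (30, 220), got {self.hr_bpm}")
        for name in ("hrv_sd", "noise_sd", "baseline_amp", "artifact_rate", "artifact_amp"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


def _child_rngs(seed: int) -> dict[str, np.random.Generator]:
    keys = ("beats", "noise", "wander", "artifacts")
    seqs = np.random.SeedSequence(seed).spawn(len(keys))
    return {k: np.random.default_rng(s) for k, s in zip(keys, seqs)}


def _beat_onsets(params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    """Jittered beat onset times covering [0, duration] with margin on both
    sides; the first onset sits half an interval before t = 0."""
    mean_int = 60.0 / params.hr_bpm
    onsets = [-1.5 * mean_int]
    while onsets[-1] < params.duration + mean_int:
        iv = rng.normal(mean_int, params.hrv_sd) if params.hrv_sd > 0 else mean_int
        iv = max(iv, 0.3 * mean_int)  # truncate: intervals stay positive
        onsets.append(onsets[-1] + iv)
    return np.asarray(onsets)


def _render_beats(t: np.ndarray, onsets: np.ndarray, shape: PulseShape,
                  sample_rate: float) -> np.ndarray:
    x = np.zeros_like(t)
    for k in range(len(onsets) - 1):
        o, interval = onsets[k], onsets[k + 1] - onsets[k]
        lo = np.searchsorted(t, o - 1.0 * interval)
        hi = np.searchsorted(t, o + 2.0 * interval)
        if lo >= hi:
            continue
        u = (t[lo:hi] - o) / interval  # beat-fraction coordinate
        x[lo:hi] += shape.systolic_amp * np.exp(
            -0.5 * ((u - shape.systolic_center) / shape.systolic_width) ** 2
        )
        x[lo:hi] += shape.dicrotic_amp * np.exp(
            -0.5 * ((u - shape.dicrotic_center) / shape.dicrotic_width) ** 2
        )
    return x


def _render_artifacts(t: np.ndarray, params: SimulationParams,
                      rng: np.random.Generator) -> np.ndarray:
    """Poisson-timed damped oscillatory transients (motion surrogate)."""
    x = np.zeros_like(t)
    n = rng.poisson(params.artifact_rate * params.duration / 60.0)
    tau, f_osc = 0.15, 6.0  # decay constant (s), oscillation frequency (Hz)
    for _ in range(n):
        t0 = rng.uniform(0.0, params.duration)
        amp = params.artifact_amp * rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.0)
        lo = np.searchsorted(t, t0)
        hi = np.searchsorted(t, t0 + 6.0 * tau)
        dt = t[lo:hi] - t0
        x[lo:hi] += amp * np.exp(-dt / tau) * np.sin(2.0 * np.pi * f_osc * dt)
    return x


def simulate_ppg(
    params: SimulationParams | None = None,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    subject_id: str = "synthetic",
    wrist: Wrist = Wrist.UNSPECIFIED,
    start_time: float = 0.0,
) -> PPGRecord:
    """Generate one continuous synthetic BVP record.

    Fully deterministic for a fixed ``params.seed``: the beat, noise, wander
    and artifact streams are drawn from independent child generators, so e.g.
    setting ``artifact_rate`` to zero leaves the rest of the signal
    bit-identical.
    """
    if params is None:
        params = SimulationParams()
    params.validate()
    rngs = _child_rngs(params.seed)
    n = int(round(params.duration * sample_rate))
    t = np.arange(n) / sample_rate

    onsets = _beat_onsets(params, rngs["beats"])
    x = _render_beats(t, onsets, params.pulse_shape, sample_rate)
    if params.baseline_amp > 0:
        phase = rngs["wander"].uniform(0.0, 2.0 * np.pi)
        x += params.baseline_amp * np.sin(2.0 * np.pi * params.baseline_freq * t + phase)
    if params.noise_sd > 0:
        x += rngs["noise"].normal(0.0, params.noise_sd, size=n)
    if params.artifact_rate > 0:
        x += _render_artifacts(t, params, rngs["artifacts"])
    return PPGRecord(start_time=start_time, sample_rate=sample_rate, samples=x,
                     subject_id=subject_id, wrist=wrist)


def simulate_run(
    params: SimulationParams | None = None,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    pj_minutes: float = 5.0,
    journey_minutes: float = 45.0,
    **kwargs,
) -> PPGRecord:
    """Generate one continuous experimental run: a pre-journey reference
    phase followed by the journey phase.

    The returned record spans ``(pj_minutes + journey_minutes)`` minutes and
    carries the phase boundary as ``pj_boundary_index =
    pj_minutes * 60 * sample_rate``.
    """
    if params is None:
        params = SimulationParams()
    total = (pj_minutes + journey_minutes) * 60.0
    record = simulate_ppg(replace(params, duration=total), sample_rate, **kwargs)
    record.pj_boundary_index = int(round(pj_minutes * 60.0 * sample_rate))
    return record


def make_polynomial_dataset(
    degree: int,
    n_waveforms: int = 30,
    waveform_len: int = 32,
    noise_sd: float = 0.0,
    seed: int | None = None,
    phase: Phase = Phase.PJ,
    index: int = 0,
) -> WaveformDataset:
    """Ground-truth fixture: waveforms sampled from one random degree-d
    polynomial plus independent noise.

    The polynomial is drawn in the Chebyshev basis on the [0, 1] local-tick
    axis with the degree-``degree`` coefficient bounded into ±[0.5, 1.5], so
    the top-degree component is guaranteed to be identifiable: any fit of
    degree < d carries an O(1) bias while fits of degree >= d are exact up to
    noise.  Built for DoP-recovery testing — a profile of the noiseless
    dataset selects exactly ``degree`` under the lowest-degree tie-break.
    """
    if degree < 1:
        raise ValidationError(f"degree must be >= 1, got {degree}")
    if waveform_len < degree + 2:
        raise ValidationError(
            f"waveform_len must be >= degree + 2 = {degree + 2}, got {waveform_len}"
        )
    if n_waveforms < 1:
        raise ValidationError("n_waveforms must be >= 1")
    rng = np.random.default_rng(seed)
    coef = rng.uniform(-1.0, 1.0, size=degree + 1)
    coef[degree] = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.5)
    poly = _cheb.Chebyshev(coef, domain=[0.0, 1.0])
    u = np.arange(waveform_len) / (waveform_len - 1)
    base = poly(u)
    waveforms = []
    for k in range(n_waveforms):
        values = base.copy()
        if noise_sd > 0:
            values = values + rng.normal(0.0, noise_sd, size=waveform_len)
        waveforms.append(Waveform(values=values, start_index=k * waveform_len))
    return WaveformDataset(phase=phase, index=index, waveforms=waveforms)
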