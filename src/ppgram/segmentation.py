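"""Trough-to-trough segmentation of a continuous BVP stream into pulses.

Each cardiac cycle of a PPG signal begins at the diastolic trough preceding
the systolic upstroke.  Pulse onsets are therefore detected as local minima of
the (optionally band-passed) signal, subject to a refractory minimum distance
derived from a maximum plausible heart rate and a prominence floor expressed
as a fraction of the signal's interquartile range.  Consecutive troughs
delimit waveforms that tile the source stream: concatenating the returned
waveforms reproduces the samples between the first and last detected trough
with no overlap and no gap.  Samples before the first trough and after the
last trough are discarded.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
from scipy import signal as sps

from .signal_io import PPGRecord, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["SegmentationParams", "Waveform", "segment", "save_waveforms", "load_waveforms"]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the trough detector.

    min_waveform_len
        Waveforms with fewer samples are discarded (a degree-20 fit on a
        handful of points is degenerate).
    max_hr_bpm
        Upper bound on plausible heart rate; sets the refractory distance
        between troughs to ``sample_rate * 60 / max_hr_bpm`` samples.
    prominence_frac
        Trough prominence floor as a fraction of the signal IQR.
    bandpass
        Optional ``(low_hz, high_hz)`` zero-phase Butterworth band-pass
        applied before trough detection only (returned waveforms always carry
        raw samples).  Off by default: clean synthetic data needs none.
    """

    min_waveform_len: int = 10
    max_hr_bpm: float = 180.0
    prominence_frac: float = 0.1
    bandpass: tuple[float, float] | None = None


@dataclass
class Waveform:
    """One segmented cardiac pulse, re-indexed to local ticks 0..len-1."""

    values: np.ndarray
    start_index: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.start_index = int(self.start_index)

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def ticks(self) -> np.ndarray:
        """Local sample indices 0, 1, ..., len-1."""
        return np.arange(self.values.size)


def _detection_signal(record: PPGRecord, params: SegmentationParams) -> np.ndarray:
    x = record.samples
    if params.bandpass is not None:
        low, high = params.bandpass
        nyq = record.sample_rate / 2.0
        sos = sps.butter(2, [low / nyq, high / nyq], btype="bandpass", output="sos")
        x = sps.sosfiltfilt(sos, x)
    return x


def segment(record: PPGRecord, params: SegmentationParams | None = None) -> list[Waveform]:
    """Partition ``record`` into trough-to-trough pulse waveforms.

    Returns an ordered list of :class:`Waveform`; an empty list (with a
    logged warning) if no troughs are found, e.g. on a constant signal.

    Raises
    ------
    ValidationError
        If the record is shorter than 2 seconds.
    """
    if params is None:
        params = SegmentationParams()
    if record.duration_seconds < 2.0:
        raise ValidationError(
            f"record too short to segment: {record.duration_seconds:.3f} s < 2 s"
        )
    x = _detection_signal(record, params)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        logger.warning("no troughs detected: signal has zero interquartile range")
        return []
    distance = max(1, int(round(record.sample_rate * 60.0 / params.max_hr_bpm)))
    troughs, _ = sps.find_peaks(
        -x, distance=distance, prominence=params.prominence_frac * iqr
    )
    if troughs.size < 2:
        logger.warning("no troughs detected (%d candidate minima)", troughs.size)
        return []

    waveforms: list[Waveform] = []
    n_short = 0
    for a, b in zip(troughs[:-1], troughs[1:]):
        if b - a < params.min_waveform_len:
            n_short += 1
            continue
        waveforms.append(Waveform(values=record.samples[a:b], start_index=int(a)))
    if n_short:
        logger.warning("discarded %d waveforms shorter than %d samples",
                       n_short, params.min_waveform_len)
    logger.debug("segmented %d waveforms from %d samples", len(waveforms), record.n_samples)
    return waveforms


# -- waveform archive ---------------------------------------------------------
# Documented JSON layout: {"sample_rate": Hz, "waveforms": [{"start_index": i,
# "values": [...]}, ...]}.  Values are raw BVP floats.

def save_waveforms(
    waveforms: list[Waveform], path: Union[str, Path], sample_rate: float | None = None
) -> None:
    payload = {
        "sample_rate": sample_rate,
        "waveforms": [
            {"start_index": w.start_index, "values": w.values.tolist()} for w in waveforms
        ],
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_waveforms(path: Union[str, Path]) -> tuple[list[Waveform], float | None]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    waveforms = [
        Waveform(values=np.asarray(w["values"], dtype=float), start_index=w["start_index"])
        for w in payload["waveforms"]
    ]
    return waveforms, payload.get("sample_rate")
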