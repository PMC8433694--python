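"""Reading and writing Empatica-E4-style blood-volume-pulse (BVP) streams.

The E4 wristband exports each sensor channel as a bare CSV: the first row is
the recording start time (UTC seconds since the Unix epoch), the second row is
the sample rate in Hz, and every following row is one sensor sample.  BVP
values are dimensionless sensor units and may be negative.  This module parses
and emits that dialect without resampling, filtering, or unit conversion:
floats survive a read/write round trip bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Union

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Wrist",
    "PPGRecord",
    "FormatError",
    "ValidationError",
    "read_e4_bvp",
    "write_e4_bvp",
]


class FormatError(ValueError):
    """A file does not conform to the expected E4 BVP dialect."""


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


class Wrist(str, Enum):
    """Which wrist a wristband was worn on."""

    LEFT = "left"
    RIGHT = "right"
    UNSPECIFIED = "unspecified"


@dataclass
class PPGRecord:
    """A continuous raw BVP stream.

    Parameters
    ----------
    start_time
        Recording start, seconds since the Unix epoch.
    sample_rate
        Sampling rate in samples/second; must be positive.
    samples
        Ordered BVP samples in sensor units (may be negative); all finite.
    subject_id
        Opaque subject label.
    wrist
        Which wrist the band was worn on.
    pj_boundary_index
        Optional sample index separating the pre-journey phase from the
        journey phase, recorded by the simulator; ``None`` for plain files.
    """

    start_time: float
    sample_rate: float
    samples: np.ndarray
    subject_id: str = "anonymous"
    wrist: Wrist = Wrist.UNSPECIFIED
    pj_boundary_index: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValidationError("samples must be a 1-D sequence")
        if not np.isfinite(self.start_time):
            raise ValidationError("start_time must be finite")
        if not (self.sample_rate > 0) or not np.isfinite(self.sample_rate):
            raise ValidationError(
                f"sample_rate must be a positive finite number, got {self.sample_rate!r}"
            )
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            bad = int(np.flatnonzero(~np.isfinite(self.samples))[0])
            raise ValidationError(f"sample {bad} is not finite")
        self.wrist = Wrist(self.wrist)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_seconds(self) -> float:
        """Record duration implied by the sample count and rate."""
        return self.n_samples / self.sample_rate


def _fmt(x: float) -> str:
    """Shortest decimal string that round-trips the float exactly."""
    return repr(float(x))


def read_e4_bvp(
    path: Union[str, Path],
    subject_id: str = "anonymous",
    wrist: Union[Wrist, str] = Wrist.UNSPECIFIED,
) -> PPGRecord:
    """Parse an E4-dialect BVP CSV into a :class:`PPGRecord`.

    Samples are passed through in file order with no resampling or filtering.

    Raises
    ------
    FormatError
        If a header row or sample row fails to parse (the message names the
        1-based offending row).
    ValidationError
        If the parsed sample rate is zero or negative.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if len(lines) < 2:
        raise FormatError(
            f"{path}: expected at least 2 header rows (start time, sample rate), "
            f"found {len(lines)} rows"
        )
    try:
        start_time = float(lines[0])
    except ValueError:
        raise FormatError(f"{path}: row 1 is not a numeric start timestamp: {lines[0]!r}") from None
    try:
        sample_rate = float(lines[1])
    except ValueError:
        raise FormatError(f"{path}: row 2 is not a numeric sample rate: {lines[1]!r}") from None
    if sample_rate <= 0:
        raise ValidationError(f"{path}: sample rate must be positive, got {sample_rate}")

    samples = np.empty(len(lines) - 2, dtype=float)
    for i, line in enumerate(lines[2:], start=3):
        try:
            samples[i - 3] = float(line)
        except ValueError:
            raise FormatError(f"{path}: row {i} is not a numeric BVP sample: {line!r}") from None
    return PPGRecord(
        start_time=start_time,
        sample_rate=sample_rate,
        samples=samples,
        subject_id=subject_id,
        wrist=Wrist(wrist),
    )


def write_e4_bvp(record: PPGRecord, path: Union[str, Path]) -> None:
    """Write ``record`` in the same two-header-row CSV dialect read by
    :func:`read_e4_bvp`.

    An empty record produces a file with exactly the two header rows; a record
    of *n* samples produces *n* + 2 rows.
    """
    path = Path(path)
    rows = [_fmt(record.start_time), _fmt(record.sample_rate)]
    rows.extend(_fmt(v) for v in record.samples)
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")
    logger.debug("wrote %d samples to %s", record.n_samples, path)
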