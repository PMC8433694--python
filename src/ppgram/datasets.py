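"""Assembly of pre-journey (PJ) and in-journey (IJ) waveform datasets.

The monitoring algorithm characterizes a patient twice: once from a
supervised 5-minute reference window recorded just before autonomous
transport begins (the PJ dataset), and repeatedly during transport from the
latest non-overlapping block of 30 consecutive pulse waveforms (the IJ
datasets).  The 30-waveform floor is the usual central-limit-theorem sample
size; a PJ window yielding fewer than 30 waveforms is rejected and a trailing
partial IJ block is discarded rather than padded.

Membership is decided by each waveform's global start index: the PJ window is
half-open, ``[0, pj_duration * sample_rate)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .segmentation import Waveform
from .signal_io import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["Phase", "WaveformDataset", "build_pj", "build_ij_stream", "split_run",
           "save_datasets", "load_datasets"]

#: Waveforms per dataset below which a dataset is not statistically meaningful.
MIN_DATASET_SIZE = 30


class Phase(str, Enum):
    PJ = "PJ"
    IJ = "IJ"


@dataclass
class WaveformDataset:
    """An ordered collection of pulse waveforms with a phase label.

    ``index`` is the ordinal of the dataset within its run: the PJ dataset has
    index 0, IJ datasets are numbered 1, 2, ... in stream order.
    """

    phase: Phase
    index: int
    waveforms: list[Waveform]

    @property
    def n_waveforms(self) -> int:
        return len(self.waveforms)

    @property
    def dataset_id(self) -> str:
        return f"{self.phase.value}-{self.index}"


def build_pj(
    waveforms: Sequence[Waveform],
    sample_rate: float,
    pj_duration: float = 300.0,
    min_waveforms: int = MIN_DATASET_SIZE,
) -> WaveformDataset:
    """Collect the PJ dataset: every waveform starting inside the first
    ``pj_duration`` seconds of the record.

    Raises
    ------
    ValidationError
        If fewer than ``min_waveforms`` waveforms qualify — below the
        central-limit-theorem sample size (N = 30) the reference dataset is
        not statistically significant.
    """
    boundary = pj_duration * sample_rate
    selected = [w for w in waveforms if w.start_index < boundary]
    if len(selected) < min_waveforms:
        raise ValidationError(
            f"PJ window produced {len(selected)} waveforms; at least "
            f"{min_waveforms} are required for statistical significance "
            f"(central limit theorem, N = {min_waveforms})"
        )
    return WaveformDataset(phase=Phase.PJ, index=0, waveforms=list(selected))


def build_ij_stream(
    waveforms: Sequence[Waveform],
    pj_boundary: int,
    ij_block_size: int = MIN_DATASET_SIZE,
) -> list[WaveformDataset]:
    """Partition post-PJ waveforms into consecutive non-overlapping IJ blocks.

    Every waveform with ``start_index >= pj_boundary`` (a global sample
    index) is assigned, in stream order, to blocks of exactly
    ``ij_block_size``; a trailing partial block is discarded and its size
    logged.  Returns ``floor(n_post_pj / ij_block_size)`` datasets.
    """
    if pj_boundary < 0:
        raise ValidationError(f"pj_boundary must be >= 0, got {pj_boundary}")
    post = [w for w in waveforms if w.start_index >= pj_boundary]
    n_blocks = len(post) // ij_block_size
    datasets = [
        WaveformDataset(
            phase=Phase.IJ,
            index=k + 1,
            waveforms=post[k * ij_block_size : (k + 1) * ij_block_size],
        )
        for k in range(n_blocks)
    ]
    leftover = len(post) - n_blocks * ij_block_size
    if leftover:
        logger.info("discarded trailing partial IJ block of %d waveforms", leftover)
    return datasets


def split_run(
    waveforms: Sequence[Waveform],
    sample_rate: float,
    pj_duration: float = 300.0,
    ij_block_size: int = MIN_DATASET_SIZE,
) -> tuple[WaveformDataset, list[WaveformDataset]]:
    """Convenience wrapper: one PJ dataset plus the IJ stream for a full run."""
    pj = build_pj(waveforms, sample_rate, pj_duration)
    boundary = int(round(pj_duration * sample_rate))
    ijs = build_ij_stream(waveforms, boundary, ij_block_size)
    return pj, ijs


# -- dataset manifests --------------------------------------------------------

def save_datasets(datasets: Sequence[WaveformDataset], path: Union[str, Path]) -> None:
    payload = [
        {
            "phase": d.phase.value,
            "index": d.index,
            "waveforms": [
                {"start_index": w.start_index, "values": w.values.tolist()}
                for w in d.waveforms
            ],
        }
        for d in datasets
    ]
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_datasets(path: Union[str, Path]) -> list[WaveformDataset]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return [
        WaveformDataset(
            phase=Phase(d["phase"]),
            index=d["index"],
            waveforms=[
                Waveform(values=np.asarray(w["values"], dtype=float),
                         start_index=w["start_index"])
                for w in d["waveforms"]
            ],
        )
        for d in payload
    ]
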