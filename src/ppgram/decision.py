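"""Equality-based DoP matching and the journey state machine.

During transport, the latest IJ dataset's DoP is compared to the PJ DoP.
Matching is strict equality: the binary output is 1 (continue) iff the two
degrees are equal, else 0 (divert to the nearest stop point).  An optional
tolerance band — match iff ``|pj - ij| <= tolerance`` — is provided as an
extension for relaxed matching; the default of 0 reproduces strict equality.

Efficacy is the ratio of positive matches to match attempts within one run:
0 means the bed was never allowed to advance, 1 means the journey completed.
``offline`` mode evaluates every IJ dataset regardless of intermediate
mismatches (the mode used for cohort efficacy analysis); ``online`` mode
halts at the first mismatch, realizing the stop-point behavior.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence, Union

from .dop_model import DoPProfile
from .signal_io import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["Mode", "TerminalState", "MatchOutcome", "JourneyResult", "match",
           "run_journey", "save_journey", "load_journey"]


class Mode(str, Enum):
    OFFLINE = "offline"
    ONLINE = "online"


class TerminalState(str, Enum):
    #: Every evaluated IJ dataset matched; the journey completes.
    ARRIVED = "arrived"
    #: Online mode halted at the first mismatch (stop point).
    STOPPED = "stopped"
    #: Offline evaluation reached end of stream despite >= 1 mismatch.
    EXHAUSTED = "exhausted"


@dataclass(frozen=True)
class MatchOutcome:
    """One PJ-vs-IJ match attempt; ``match`` is 1 iff the DoPs agree."""

    ij_index: int
    pj_dop: int
    ij_dop: int
    match: int


@dataclass
class JourneyResult:
    """Ordered match outcomes of one run plus the efficacy statistic."""

    outcomes: list[MatchOutcome]
    efficacy: float
    mode: Mode
    terminal_state: TerminalState
    subject_id: str = ""
    wrist: str = "unspecified"


def match(pj_dop: int, ij_dop: int, tolerance: int = 0) -> int:
    """Binary DoP match: 1 iff ``|pj_dop - ij_dop| <= tolerance`` (default:
    strict equality), else 0."""
    if pj_dop < 1 or ij_dop < 1:
        raise ValidationError(f"degrees must be >= 1, got ({pj_dop}, {ij_dop})")
    return int(abs(pj_dop - ij_dop) <= tolerance)


def run_journey(
    pj_profile: DoPProfile,
    ij_profiles: Sequence[DoPProfile],
    mode: Union[Mode, str] = Mode.OFFLINE,
    tolerance: int = 0,
    subject_id: str = "",
    wrist: str = "unspecified",
) -> JourneyResult:
    """Match the PJ DoP against successive IJ DoPs and compute efficacy.

    Offline mode evaluates every IJ profile; online mode stops at the first
    mismatch.  Efficacy = positive matches / attempts over the evaluated
    outcomes only.

    Raises
    ------
    ValidationError
        If ``ij_profiles`` is empty (efficacy is undefined for 0 attempts).
    """
    mode = Mode(mode)
    if not ij_profiles:
        raise ValidationError("at least one IJ profile is required; efficacy "
                              "is undefined for zero match attempts")
    pj_dop = pj_profile.selected_dop
    outcomes: list[MatchOutcome] = []
    stopped = False
    for k, ij in enumerate(ij_profiles, start=1):
        m = match(pj_dop, ij.selected_dop, tolerance)
        outcomes.append(MatchOutcome(ij_index=k, pj_dop=pj_dop,
                                     ij_dop=ij.selected_dop, match=m))
        if mode is Mode.ONLINE and m == 0:
            stopped = True
            break
    n_pos = sum(o.match for o in outcomes)
    efficacy = n_pos / len(outcomes)
    if stopped:
        terminal = TerminalState.STOPPED
    elif n_pos == len(outcomes):
        terminal = TerminalState.ARRIVED
    else:
        terminal = TerminalState.EXHAUSTED
    logger.debug("journey %s/%s: %d/%d matches, efficacy %.3f, %s",
                 subject_id, wrist, n_pos, len(outcomes), efficacy, terminal.value)
    return JourneyResult(outcomes=outcomes, efficacy=efficacy, mode=mode,
                         terminal_state=terminal, subject_id=subject_id, wrist=wrist)


# -- journey logs (JSON lines, one MatchOutcome per line, trailing summary) ---

def save_journey(result: JourneyResult, path: Union[str, Path]) -> None:
    lines = [
        json.dumps({"ij_index": o.ij_index, "pj_dop": o.pj_dop,
                    "ij_dop": o.ij_dop, "match": o.match})
        for o in result.outcomes
    ]
    lines.append(json.dumps({
        "efficacy": result.efficacy,
        "mode": result.mode.value,
        "terminal_state": result.terminal_state.value,
        "subject_id": result.subject_id,
        "wrist": result.wrist,
    }))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_journey(path: Union[str, Path]) -> JourneyResult:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    *outcome_lines, summary_line = lines
    outcomes = [MatchOutcome(**json.loads(ln)) for ln in outcome_lines]
    summary = json.loads(summary_line)
    return JourneyResult(
        outcomes=outcomes,
        efficacy=summary["efficacy"],
        mode=Mode(summary["mode"]),
        terminal_state=TerminalState(summary["terminal_state"]),
        subject_id=summary.get("subject_id", ""),
        wrist=summary.get("wrist", "unspecified"),
    )
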