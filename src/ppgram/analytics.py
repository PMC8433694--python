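"""Cohort-level summaries: DoP distributions, CVSM spreads, extremes, efficacy.

Each dataset contributes exactly one entry — its selected DoP and the CVSM at
that DoP — to the cohort views.  The DoP histogram exposes both the peak set
(all degrees attaining the maximum count) and a single *dominant* degree,
where count ties break to the degree with the higher mean CVSM among its
selecting datasets (better data accountability).  Plotting helpers mirror the
standard panels (overlaid-pulse scatter with the fitted curve, histograms,
per-degree spread bars, a per-subject efficacy heatmap); they are thin
matplotlib wrappers and side-effect-only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .datasets import WaveformDataset
from .decision import JourneyResult
from .dop_model import DoPProfile, pool_points
from .signal_io import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "DopHistogram", "SpreadStats", "ExtremeEntry", "EfficacySummary",
    "CohortSummary", "dop_distribution", "cvsm_spread", "rank_extremes",
    "efficacy_summary", "summarize_cohort",
    "plot_dataset_fit", "plot_dop_distribution", "plot_cvsm_spread",
    "plot_efficacy_heatmap",
]


@dataclass
class DopHistogram:
    """Counts of selected DoP per degree; only degrees with >= 1 selection
    appear."""

    counts: dict[int, int]
    peaks: list[int]          # all degrees attaining the maximum count
    dominant: int             # count ties broken by higher mean selected CVSM

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class SpreadStats:
    degree: int
    n: int
    mean: float
    min: float
    max: float
    values: list[float]


@dataclass
class ExtremeEntry:
    dataset_id: str
    cvsm: float
    dop: int


@dataclass
class EfficacySummary:
    mean_efficacy: float
    per_subject: dict[str, dict[str, float]]  # subject -> wrist -> efficacy
    per_wrist: dict[str, list[float]]


@dataclass
class CohortSummary:
    """All cohort views bundled, keyed by phase label ('PJ'/'IJ')."""

    dop_histogram: dict[str, DopHistogram]
    cvsm_by_degree: dict[str, dict[int, SpreadStats]]
    extremes: dict[str, dict[str, list[ExtremeEntry]]]
    efficacy: EfficacySummary | None = None


def dop_distribution(profiles: Sequence[DoPProfile]) -> DopHistogram:
    """Histogram of selected DoPs; one unit of mass per profile."""
    if not profiles:
        raise ValidationError("dop_distribution requires at least one profile")
    counts: dict[int, int] = {}
    for p in profiles:
        counts[p.selected_dop] = counts.get(p.selected_dop, 0) + 1
    max_count = max(counts.values())
    peaks = sorted(d for d, c in counts.items() if c == max_count)
    if len(peaks) == 1:
        dominant = peaks[0]
    else:
        # break count ties by higher mean CVSM among the selecting datasets
        def mean_cvsm(d: int) -> float:
            vals = [p.selected_cvsm for p in profiles if p.selected_dop == d]
            return float(np.mean(vals))
        dominant = max(peaks, key=lambda d: (mean_cvsm(d), -d))
    return DopHistogram(counts=dict(sorted(counts.items())), peaks=peaks,
                        dominant=dominant)


def cvsm_spread(profiles: Sequence[DoPProfile]) -> dict[int, SpreadStats]:
    """Selected (DoP, CVSM) pairs grouped by degree, with occurrence count,
    mean and extremes.  Degrees never selected are absent."""
    if not profiles:
        raise ValidationError("cvsm_spread requires at least one profile")
    groups: dict[int, list[float]] = {}
    for p in profiles:
        groups.setdefault(p.selected_dop, []).append(p.selected_cvsm)
    return {
        d: SpreadStats(degree=d, n=len(v), mean=float(np.mean(v)),
                       min=float(np.min(v)), max=float(np.max(v)), values=v)
        for d, v in sorted(groups.items())
    }


def rank_extremes(
    profiles: Sequence[DoPProfile], k: int = 5
) -> tuple[list[ExtremeEntry], list[ExtremeEntry]]:
    """Top-k (descending CVSM) and worst-k (ascending CVSM) datasets.

    Ties keep a stable order by dataset id.  With fewer than ``k`` profiles
    the panels are truncated; top and worst may overlap.
    """
    entries = [ExtremeEntry(p.dataset_id, p.selected_cvsm, p.selected_dop)
               for p in profiles]
    by_id = sorted(entries, key=lambda e: e.dataset_id)
    top = sorted(by_id, key=lambda e: -e.cvsm)[:k]
    worst = sorted(by_id, key=lambda e: e.cvsm)[:k]
    return top, worst


def efficacy_summary(results: Sequence[JourneyResult]) -> EfficacySummary:
    """Cohort mean efficacy plus per-subject and per-wrist breakdowns."""
    if not results:
        raise ValidationError("efficacy_summary requires at least one journey")
    per_subject: dict[str, dict[str, float]] = {}
    per_wrist: dict[str, list[float]] = {}
    for r in results:
        per_subject.setdefault(r.subject_id, {})[r.wrist] = r.efficacy
        per_wrist.setdefault(r.wrist, []).append(r.efficacy)
    mean = float(np.mean([r.efficacy for r in results]))
    return EfficacySummary(mean_efficacy=mean, per_subject=per_subject,
                           per_wrist=per_wrist)


def summarize_cohort(
    profiles_by_phase: Mapping[str, Sequence[DoPProfile]],
    journeys: Sequence[JourneyResult] | None = None,
    k_extremes: int = 5,
) -> CohortSummary:
    hist = {ph: dop_distribution(ps) for ph, ps in profiles_by_phase.items() if ps}
    spread = {ph: cvsm_spread(ps) for ph, ps in profiles_by_phase.items() if ps}
    extremes = {}
    for ph, ps in profiles_by_phase.items():
        if not ps:
            continue
        top, worst = rank_extremes(ps, k_extremes)
        extremes[ph] = {"top": top, "worst": worst}
    eff = efficacy_summary(journeys) if journeys else None
    return CohortSummary(dop_histogram=hist, cvsm_by_degree=spread,
                         extremes=extremes, efficacy=eff)


# -- plotting (side-effect-only; excluded from the tested numerical core) -----

def _require_axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt
        _, ax = plt.subplots()
    return ax


def plot_dataset_fit(dataset: WaveformDataset, profile_: DoPProfile, ax=None):
    """Overlaid pulse scatter with the selected-DoP fitted curve."""
    from numpy.polynomial import chebyshev as _cheb

    ax = _require_axes(ax)
    pts = pool_points(dataset)
    ax.plot(pts.x, pts.y, "x", color="green", ms=2, alpha=0.5)
    fit = _cheb.Chebyshev.fit(pts.x, pts.y, deg=profile_.selected_dop,
                              domain=[0.0, 1.0])
    grid = np.linspace(0.0, 1.0, 200)
    ax.plot(grid, fit(grid), "r-", lw=2)
    ax.set_xlabel("local tick (rescaled)")
    ax.set_ylabel("BVP")
    ax.set_title(f"{profile_.dataset_id}: DoP {profile_.selected_dop}, "
                 f"CVSM {profile_.selected_cvsm:.3f}")
    return ax


def plot_dop_distribution(hist: DopHistogram, ax=None, label: str = ""):
    ax = _require_axes(ax)
    degrees = sorted(hist.counts)
    ax.bar(degrees, [hist.counts[d] for d in degrees])
    ax.set_xlabel("DoP")
    ax.set_ylabel("datasets")
    ax.set_title(f"{label} DoP distribution (dominant {hist.dominant})".strip())
    return ax


def plot_cvsm_spread(spread: Mapping[int, SpreadStats], ax=None, label: str = ""):
    ax = _require_axes(ax)
    for d, s in spread.items():
        ax.vlines(d, s.min, s.max, color="C0")
        ax.plot(d, s.mean, "o", color="C1")
    ax.set_xlabel("DoP")
    ax.set_ylabel("CVSM")
    ax.set_title(f"{label} CVSM spread per DoP".strip())
    return ax


def plot_efficacy_heatmap(summary: EfficacySummary, ax=None):
    ax = _require_axes(ax)
    subjects = sorted(summary.per_subject)
    wrists = sorted({w for d in summary.per_subject.values() for w in d})
    grid = np.full((len(wrists), len(subjects)), np.nan)
    for j, s in enumerate(subjects):
        for i, w in enumerate(wrists):
            if w in summary.per_subject[s]:
                grid[i, j] = summary.per_subject[s][w]
    im = ax.imshow(grid, aspect="auto", vmin=0.0, vmax=1.0, cmap="viridis")
    ax.set_yticks(range(len(wrists)), wrists)
    ax.set_xticks(range(len(subjects)), subjects, rotation=90, fontsize=6)
    ax.figure.colorbar(im, ax=ax, label="efficacy")
    ax.set_title(f"Efficacy per subject (mean {summary.mean_efficacy:.2f})")
    return ax
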