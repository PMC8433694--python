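"""Degree-of-polynomial (DoP) selection by cross-validation score mean (CVSM).

A dataset of pulse waveforms is summarized by one number: the degree of the
polynomial regression that best explains BVP as a function of the local tick
within a pulse.  All waveforms of a dataset are pooled on a shared local tick
axis (rescaled to [0, 1] for conditioning), then for every candidate degree
1..d_max a k-fold cross-validation is run and the mean held-out R² — the
cross-validation score mean, CVSM — is recorded.  The selected DoP is the
smallest degree whose CVSM ties the maximum (parsimony tie-break, judged at
numerical precision ``tie_tol``).

CVSM is unbounded below (held-out R² of a bad model can be negative) and
bounded above by 1.  The same fold assignment is reused across all degrees of
a profile so that degrees are compared on identical splits; fold shuffling is
seeded and the seed is recorded in the profile.

Numerical notes: fits use the Chebyshev basis on the rescaled predictor — a
degree-20 monomial (Vandermonde) design is numerically unusable — via a
least-squares solve that falls back to a rank-truncated pseudo-inverse
(with a logged warning) on singular designs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence, Union

import numpy as np
from numpy.polynomial import chebyshev as _cheb
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold, ShuffleSplit

from .datasets import WaveformDataset
from .signal_io import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionPoints",
    "DoPProfile",
    "pool_points",
    "make_cv_splits",
    "fit_cvsm",
    "profile",
    "save_profiles",
    "load_profiles",
]

#: Degree search range used throughout the pipeline (1st..20th DoP).
DEFAULT_D_MAX = 20
#: Cross-validation folds per dataset.
DEFAULT_FOLDS = 5
#: Two CVSM values closer than this are considered tied (numerical precision).
DEFAULT_TIE_TOL = 1e-9

CVScheme = Literal["kfold", "repeated_split"]


@dataclass
class RegressionPoints:
    """Pooled (local tick, BVP) pairs of one dataset, tick rescaled to [0, 1]."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValidationError("x and y must be 1-D arrays of equal length")

    @property
    def n_points(self) -> int:
        return int(self.x.size)


@dataclass
class DoPProfile:
    """Per-degree CVSM curve of one dataset and the selected DoP.

    ``selected_dop`` is the smallest degree whose CVSM lies within
    ``tie_tol`` of the maximum CVSM.
    """

    degrees: np.ndarray
    cvsm: np.ndarray
    selected_dop: int
    selected_cvsm: float
    seed: int
    dataset_id: str = ""

    def cvsm_at(self, degree: int) -> float:
        return float(self.cvsm[int(np.flatnonzero(self.degrees == degree)[0])])


def pool_points(dataset: WaveformDataset) -> RegressionPoints:
    """Pool every sample of every waveform into one regression point cloud.

    Each sample contributes one (local tick, BVP) pair; ticks are divided by
    ``max(len(waveform)) - 1`` over the dataset so the predictor lies in
    [0, 1].  The pooled multiset is invariant to waveform order.

    Raises
    ------
    ValidationError
        If the dataset is empty or every waveform is shorter than 2 samples.
    """
    if not dataset.waveforms:
        raise ValidationError("cannot pool an empty dataset")
    max_len = max(len(w) for w in dataset.waveforms)
    if max_len < 2:
        raise ValidationError("all waveforms shorter than 2 samples; nothing to regress")
    scale = float(max_len - 1)
    xs = np.concatenate([w.ticks / scale for w in dataset.waveforms])
    ys = np.concatenate([w.values for w in dataset.waveforms])
    return RegressionPoints(x=xs, y=ys)


def make_cv_splits(
    n_points: int,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    cv_scheme: CVScheme = "kfold",
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded (train, test) index pairs shared across the degrees of a profile.

    ``kfold`` is k-fold cross-validation with shuffling (the default reading
    of "averaged over 5 modelings"); ``repeated_split`` draws ``folds``
    independent 80/20 shuffle splits instead.
    """
    if n_points < folds:
        raise ValidationError(f"{n_points} points cannot be split into {folds} folds")
    idx = np.arange(n_points)
    if cv_scheme == "kfold":
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    elif cv_scheme == "repeated_split":
        splitter = ShuffleSplit(n_splits=folds, test_size=0.2, random_state=seed)
    else:
        raise ValidationError(f"unknown cv_scheme: {cv_scheme!r}")
    return [(train, test) for train, test in splitter.split(idx)]


def _cheb_fit_predict(
    x_train: np.ndarray, y_train: np.ndarray, x_eval: np.ndarray, degree: int
) -> np.ndarray:
    """Least-squares polynomial fit of ``degree`` in the Chebyshev basis on
    domain [0, 1], evaluated at ``x_eval``.  Rank-deficient designs are
    resolved by the pseudo-inverse (lstsq) with a logged warning."""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", np.exceptions.RankWarning)
        fit = _cheb.Chebyshev.fit(x_train, y_train, deg=degree, domain=[0.0, 1.0])
        if any(issubclass(w.category, np.exceptions.RankWarning) for w in caught):
            logger.warning(
                "rank-deficient degree-%d design (%d points); using regularized solve",
                degree, x_train.size,
            )
    return fit(x_eval)


def fit_cvsm(
    points: RegressionPoints,
    degree: int,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    cv_scheme: CVScheme = "kfold",
    splits: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
) -> float:
    """Cross-validation score mean for one polynomial degree.

    Per fold, a least-squares polynomial of ``degree`` is fit on the training
    split and scored by R² (coefficient of determination) on the held-out
    split; the mean of the fold scores is returned.  Pass precomputed
    ``splits`` to score several degrees on identical folds.
    """
    if degree < 1:
        raise ValidationError(f"degree must be >= 1, got {degree}")
    if splits is None:
        splits = make_cv_splits(points.n_points, folds, seed, cv_scheme)
    scores = []
    for train, test in splits:
        if train.size < degree + 1:
            raise ValidationError(
                f"degree {degree} needs {degree + 1} training points; fold has {train.size}"
            )
        pred = _cheb_fit_predict(points.x[train], points.y[train], points.x[test], degree)
        scores.append(r2_score(points.y[test], pred))
    return float(np.mean(scores))


def profile(
    dataset: WaveformDataset,
    d_max: int = DEFAULT_D_MAX,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    cv_scheme: CVScheme = "kfold",
    tie_tol: float = DEFAULT_TIE_TOL,
) -> DoPProfile:
    """Score every degree 1..d_max on one shared fold assignment and select
    the DoP.

    The fold partition is drawn once per dataset and reused across degrees so
    that degrees are compared on identical splits.  Ties in CVSM (within
    ``tie_tol``) break to the lowest degree.
    """
    points = pool_points(dataset)
    splits = make_cv_splits(points.n_points, folds, seed, cv_scheme)
    degrees = np.arange(1, d_max + 1)
    cvsm = np.array([
        fit_cvsm(points, int(d), folds=folds, seed=seed, cv_scheme=cv_scheme, splits=splits)
        for d in degrees
    ])
    best = float(cvsm.max())
    selected = int(degrees[np.flatnonzero(cvsm >= best - tie_tol)[0]])
    prof = DoPProfile(
        degrees=degrees,
        cvsm=cvsm,
        selected_dop=selected,
        selected_cvsm=float(cvsm[selected - 1]),
        seed=int(seed),
        dataset_id=dataset.dataset_id,
    )
    logger.debug("%s: selected DoP %d (CVSM %.4f)", dataset.dataset_id, selected, best)
    return prof


# -- profile archives ---------------------------------------------------------

def _profile_to_dict(p: DoPProfile) -> dict:
    return {
        "dataset_id": p.dataset_id,
        "degrees": p.degrees.tolist(),
        "cvsm": p.cvsm.tolist(),
        "selected_dop": p.selected_dop,
        "selected_cvsm": p.selected_cvsm,
        "seed": p.seed,
    }


def save_profiles(profiles: Sequence[DoPProfile], path: Union[str, Path]) -> None:
    Path(path).write_text(
        json.dumps([_profile_to_dict(p) for p in profiles]), encoding="utf-8"
    )


def load_profiles(path: Union[str, Path]) -> list[DoPProfile]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return [
        DoPProfile(
            degrees=np.asarray(d["degrees"], dtype=int),
            cvsm=np.asarray(d["cvsm"], dtype=float),
            selected_dop=d["selected_dop"],
            selected_cvsm=d["selected_cvsm"],
            seed=d["seed"],
            dataset_id=d.get("dataset_id", ""),
        )
        for d in payload
    ]
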