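"""Polynomial CV scoring and DoP selection against brute-force oracles."""

import numpy as np
import pytest

from ppgram import (Phase, ValidationError, WaveformDataset, fit_cvsm,
                    make_cv_splits, make_polynomial_dataset, pool_points,
                    profile)
from ppgram.dop_model import RegressionPoints, load_profiles, save_profiles
from ppgram.segmentation import Waveform


def brute_force_cvsm(x, y, degree, splits):
    """Independent fold-by-fold oracle: monomial-basis normal-equation fit
    via lstsq plus a hand-written R², averaged over the folds."""
    scores = []
    for train, test in splits:
        V = np.vander(x[train], degree + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(V, y[train], rcond=None)
        pred = np.vander(x[test], degree + 1, increasing=True) @ coef
        ss_res = float(((y[test] - pred) ** 2).sum())
        ss_tot = float(((y[test] - y[test].mean()) ** 2).sum())
        scores.append(1.0 - ss_res / ss_tot)
    return float(np.mean(scores))


def uniform_dataset(y_per_waveform, phase=Phase.PJ):
    wfs = [Waveform(values=np.asarray(v, dtype=float), start_index=k * len(v))
           for k, v in enumerate(y_per_waveform)]
    return WaveformDataset(phase=phase, index=0, waveforms=wfs)


# -- pool_points --------------------------------------------------------------

def test_pool_points_counts_and_rescaling():
    ds = make_polynomial_dataset(3, n_waveforms=30, waveform_len=48, seed=0)
    pts = pool_points(ds)
    assert pts.n_points == 30 * 48
    assert pts.x.min() == 0.0 and pts.x.max() == 1.0


def test_pool_points_single_waveform_grid():
    ds = uniform_dataset([np.arange(5.0)])
    pts = pool_points(ds)
    assert np.allclose(pts.x, [0.0, 0.25, 0.5, 0.75, 1.0])


def test_pool_points_waveform_order_invariance(rng):
    ds = uniform_dataset([rng.normal(size=20) for _ in range(10)])
    shuffled = WaveformDataset(phase=ds.phase, index=0,
                               waveforms=list(reversed(ds.waveforms)))
    a, b = pool_points(ds), pool_points(shuffled)
    order = lambda p: np.lexsort((p.y, p.x))
    assert np.array_equal(a.x[order(a)], b.x[order(b)])
    assert np.array_equal(a.y[order(a)], b.y[order(b)])


def test_pool_points_degenerate_dataset_rejected():
    ds = uniform_dataset([[1.0], [2.0]])
    with pytest.raises(ValidationError, match="shorter than 2"):
        pool_points(ds)


# -- fit_cvsm -----------------------------------------------------------------

def test_noiseless_linear_scores_one():
    x = np.linspace(0, 1, 40)
    pts = RegressionPoints(x=x, y=2 * x + 1)
    assert fit_cvsm(pts, degree=1, folds=5, seed=0) == pytest.approx(1.0, abs=1e-9)


@pytest.mark.parametrize("n_points, folds, degree",
                         [(8, 2, 1), (12, 3, 2), (20, 5, 3), (20, 2, 4)])
def test_cvsm_matches_brute_force_oracle(rng, n_points, folds, degree):
    """fit_cvsm equals an independently coded fold-by-fold R² mean to 1e-9
    on fixed small point sets, including the hand-checkable 2-fold/8-point
    case."""
    x = rng.uniform(0, 1, n_points)
    y = rng.normal(size=n_points)
    splits = make_cv_splits(n_points, folds, seed=7)
    ours = fit_cvsm(RegressionPoints(x=x, y=y), degree, splits=splits)
    oracle = brute_force_cvsm(x, y, degree, splits)
    assert ours == pytest.approx(oracle, abs=1e-9)


def test_white_noise_scores_near_zero_or_negative(rng):
    """BVP independent of tick: held-out R² is near zero and goes negative
    at high degrees."""
    wfs = [rng.normal(size=48) for _ in range(30)]
    pts = pool_points(uniform_dataset(wfs))
    scores = [fit_cvsm(pts, d, seed=3) for d in range(1, 21)]
    assert max(scores) <= 0.05
    assert min(scores) < 0.0


def test_degree_exceeding_training_split_rejected():
    pts = RegressionPoints(x=np.linspace(0, 1, 8), y=np.zeros(8))
    with pytest.raises(ValidationError, match="training points"):
        fit_cvsm(pts, degree=6, folds=2, seed=0)
    with pytest.raises(ValidationError, match=">= 1"):
        fit_cvsm(pts, degree=0)


def test_repeated_split_scheme_available():
    x = np.linspace(0, 1, 50)
    pts = RegressionPoints(x=x, y=x ** 2)
    s = fit_cvsm(pts, degree=2, folds=5, seed=0, cv_scheme="repeated_split")
    assert s == pytest.approx(1.0, abs=1e-9)


# -- profile ------------------------------------------------------------------

@pytest.mark.parametrize("degree", range(1, 11))
def test_noiseless_polynomial_recovery(degree):
    """Noiseless degree-d data scores ~1 at every degree >= d, so the
    lowest-degree tie-break must return exactly d."""
    ds = make_polynomial_dataset(degree, n_waveforms=10, waveform_len=32,
                                 noise_sd=0.0, seed=degree)
    prof = profile(ds, d_max=20, folds=5, seed=99)
    assert prof.selected_dop == degree
    assert prof.selected_cvsm == pytest.approx(1.0, abs=1e-9)


def test_profile_invariants_and_reproducibility():
    ds = make_polynomial_dataset(5, n_waveforms=12, waveform_len=24,
                                 noise_sd=0.05, seed=3)
    p1 = profile(ds, d_max=20, folds=5, seed=11)
    p2 = profile(ds, d_max=20, folds=5, seed=11)
    assert np.array_equal(p1.cvsm, p2.cvsm) and p1.selected_dop == p2.selected_dop
    assert np.all(p1.cvsm <= 1 + 1e-12)
    assert p1.cvsm[p1.selected_dop - 1] >= p1.cvsm.max() - 1e-9
    ties = np.flatnonzero(p1.cvsm >= p1.cvsm.max() - 1e-9)
    assert p1.selected_dop == int(p1.degrees[ties[0]])
    assert p1.seed == 11


def test_profile_d_max_one():
    ds = make_polynomial_dataset(1, n_waveforms=8, waveform_len=16, seed=0)
    prof = profile(ds, d_max=1, folds=5, seed=0)
    assert len(prof.cvsm) == 1 and prof.selected_dop == 1


def test_profile_archive_round_trip(tmp_path):
    ds = make_polynomial_dataset(4, seed=1)
    prof = profile(ds, seed=5)
    save_profiles([prof], tmp_path / "p.json")
    back = load_profiles(tmp_path / "p.json")[0]
    assert back.selected_dop == prof.selected_dop
    assert back.dataset_id == prof.dataset_id
    assert np.allclose(back.cvsm, prof.cvsm)
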