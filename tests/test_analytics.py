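"""Cohort summaries: histograms, spreads, extreme ranking, efficacy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppgram import (ValidationError, cvsm_spread, dop_distribution,
                    efficacy_summary, make_polynomial_dataset, profile,
                    rank_extremes, run_journey, summarize_cohort)
from ppgram.decision import JourneyResult, Mode, TerminalState
from ppgram.dop_model import DoPProfile


def prof(dop, cvsm, dataset_id="D"):
    degrees = np.arange(1, 21)
    curve = np.full(20, -1.0)
    curve[dop - 1] = cvsm
    return DoPProfile(degrees=degrees, cvsm=curve, selected_dop=dop,
                      selected_cvsm=cvsm, seed=0, dataset_id=dataset_id)


def journey(efficacy, subject, wrist):
    return JourneyResult(outcomes=[], efficacy=efficacy, mode=Mode.OFFLINE,
                         terminal_state=TerminalState.EXHAUSTED,
                         subject_id=subject, wrist=wrist)


def test_dop_distribution_example():
    h = dop_distribution([prof(8, 0.5), prof(8, 0.4), prof(7, 0.6)])
    assert h.counts == {7: 1, 8: 2}
    assert h.peaks == [8] and h.dominant == 8
    assert h.total == 3


def test_dop_distribution_single_profile():
    h = dop_distribution([prof(5, 0.2)])
    assert h.counts == {5: 1} and h.peaks == [5]


def test_dominant_breaks_count_ties_by_mean_cvsm():
    """Two equally frequent peaks: the dominant DoP is the one whose
    selecting datasets have the higher mean CVSM."""
    profiles = [prof(7, 0.70), prof(7, 0.72), prof(8, 0.80), prof(8, 0.78)]
    h = dop_distribution(profiles)
    assert h.peaks == [7, 8]
    assert h.dominant == 8


@settings(deadline=None, max_examples=40)
@given(dops=st.lists(st.integers(1, 20), min_size=1, max_size=60))
def test_histogram_mass_conservation(dops):
    profiles = [prof(d, 0.5, dataset_id=f"D{i}") for i, d in enumerate(dops)]
    h = dop_distribution(profiles)
    assert sum(h.counts.values()) == len(profiles)
    assert set(h.counts) == set(dops)


def test_cvsm_spread_example_and_bounds():
    spread = cvsm_spread([prof(8, 0.4), prof(8, 0.6), prof(3, 0.1)])
    assert spread[8].n == 2 and spread[8].mean == pytest.approx(0.5)
    assert 5 not in spread  # degree never selected is absent
    for s in spread.values():
        assert s.min <= s.mean <= s.max


def test_rank_extremes_against_sort_oracle(rng):
    profiles = [prof(int(rng.integers(1, 21)), float(rng.uniform(-1, 1)),
                     dataset_id=f"D{i:02d}") for i in range(12)]
    top, worst = rank_extremes(profiles, k=5)
    by_cvsm = sorted(p.selected_cvsm for p in profiles)
    assert [e.cvsm for e in worst] == by_cvsm[:5]
    assert [e.cvsm for e in top] == by_cvsm[::-1][:5]


def test_rank_extremes_small_panels_and_k1():
    profiles = [prof(5, v, dataset_id=f"D{i}") for i, v in enumerate((0.1, 0.9, 0.5))]
    top, worst = rank_extremes(profiles, k=5)
    assert len(top) == len(worst) == 3  # truncated panels, overlap allowed
    top1, worst1 = rank_extremes(profiles, k=1)
    assert top1[0].cvsm == 0.9 and worst1[0].cvsm == 0.1


def test_efficacy_summary_mean_and_breakdown():
    results = [journey(0.2, "S1", "left"), journey(0.2, "S1", "right"),
               journey(0.2, "S2", "left")]
    s = efficacy_summary(results)
    assert s.mean_efficacy == pytest.approx(0.2)
    assert s.per_subject["S1"]["right"] == 0.2
    assert s.per_wrist["left"] == [0.2, 0.2]
    vals = [0.2, 0.2, 0.2]
    assert s.mean_efficacy == pytest.approx(sum(vals) / len(vals))


def test_empty_inputs_rejected():
    for fn in (dop_distribution, cvsm_spread, efficacy_summary):
        with pytest.raises(ValidationError):
            fn([])


def test_homogeneous_cohort_has_single_dominant_peak():
    """A cohort built from one ground-truth template concentrates its DoP
    histogram on the template degree."""
    profiles = [profile(make_polynomial_dataset(6, n_waveforms=10,
                                                waveform_len=24, seed=s),
                        seed=s)
                for s in range(8)]
    h = dop_distribution(profiles)
    assert h.peaks == [6] and h.counts[6] == 8


def test_plot_helpers_render_without_error(tmp_path):
    """Plotting is side-effect-only; the panels must at least render."""
    import matplotlib.pyplot as plt

    from ppgram.analytics import (plot_cvsm_spread, plot_dataset_fit,
                                  plot_dop_distribution, plot_efficacy_heatmap)

    ds = make_polynomial_dataset(4, n_waveforms=5, waveform_len=16, seed=0)
    p = profile(ds, seed=0)
    axes = [
        plot_dataset_fit(ds, p),
        plot_dop_distribution(dop_distribution([p]), label="PJ"),
        plot_cvsm_spread(cvsm_spread([p]), label="PJ"),
        plot_efficacy_heatmap(efficacy_summary([journey(0.4, "S1", "left")])),
    ]
    for ax in axes:
        ax.figure.savefig(tmp_path / f"{id(ax)}.png")
        plt.close(ax.figure)


def test_summarize_cohort_bundles_phases():
    pj = [prof(8, 0.5, "PJ-0")]
    ij = [prof(8, 0.9, "IJ-1"), prof(7, 0.3, "IJ-2")]
    s = summarize_cohort({"PJ": pj, "IJ": ij},
                         journeys=[journey(0.5, "S1", "left")])
    assert s.dop_histogram["IJ"].total == 2
    assert s.extremes["IJ"]["top"][0].dataset_id == "IJ-1"
    assert s.efficacy.mean_efficacy == 0.5
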