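"""End-to-end run orchestration: simulate → segment → datasets → profiles →
decision → cohort summary, with a round-trippable configuration object.

Defaults equal the standard study conditions: a 5-minute pre-journey window,
in-journey blocks of 30 waveforms, degree search 1..20, 5-fold
cross-validation, strict equality matching evaluated offline.  Identical
config and seeds yield byte-identical summary JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import yaml

from . import analytics, datasets, decision, dop_model, segmentation, signal_io, synthetic

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "run_cohort",
           "load_config", "save_config", "summary_to_dict"]


@dataclass
class RunConfig:
    """All pipeline parameter groups; round-trips losslessly through YAML."""

    seed: int = 0
    sample_rate: float = synthetic.DEFAULT_SAMPLE_RATE
    pj_minutes: float = 5.0
    journey_minutes: float = 45.0
    ij_block_size: int = 30
    d_max: int = dop_model.DEFAULT_D_MAX
    folds: int = dop_model.DEFAULT_FOLDS
    cv_scheme: str = "kfold"
    tie_tol: float = dop_model.DEFAULT_TIE_TOL
    mode: str = "offline"
    tolerance: int = 0
    segmentation: segmentation.SegmentationParams = field(
        default_factory=segmentation.SegmentationParams)
    simulation: synthetic.SimulationParams = field(
        default_factory=synthetic.SimulationParams)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        bp = d["segmentation"]["bandpass"]
        if bp is not None:
            d["segmentation"]["bandpass"] = list(bp)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        seg = dict(d.pop("segmentation", {}))
        if seg.get("bandpass") is not None:
            seg["bandpass"] = tuple(seg["bandpass"])
        sim = dict(d.pop("simulation", {}))
        shape = synthetic.PulseShape(**sim.pop("pulse_shape", {}))
        return cls(
            segmentation=segmentation.SegmentationParams(**seg),
            simulation=synthetic.SimulationParams(pulse_shape=shape, **sim),
            **d,
        )


def save_config(config: RunConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True),
                          encoding="utf-8")


def load_config(path: Union[str, Path]) -> RunConfig:
    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))


@dataclass
class PipelineResult:
    record: signal_io.PPGRecord
    waveforms: list
    pj_dataset: datasets.WaveformDataset
    ij_datasets: list
    pj_profile: dop_model.DoPProfile
    ij_profiles: list
    journey: decision.JourneyResult
    summary: analytics.CohortSummary


def _profile_seed(master_seed: int, dataset_index: int) -> int:
    """Deterministic per-dataset fold-shuffle seed derived from the master."""
    return int(np.random.SeedSequence(entropy=master_seed,
                                      spawn_key=(dataset_index,)
                                      ).generate_state(1)[0] % (2 ** 31))


def run_pipeline(
    config: RunConfig,
    record: signal_io.PPGRecord | None = None,
    outdir: Union[str, Path, None] = None,
) -> PipelineResult:
    """Execute the full monitoring pipeline on ``record`` (simulated from
    ``config.simulation`` when omitted) and return all stage artifacts.

    When ``outdir`` is given, every intermediate artifact is persisted in a
    format its owning module can re-load.
    """
    t0 = time.perf_counter()
    if record is None:
        record = synthetic.simulate_run(
            config.simulation, config.sample_rate,
            pj_minutes=config.pj_minutes, journey_minutes=config.journey_minutes)
        logger.info("simulated %.0f s of PPG (%d samples)",
                    record.duration_seconds, record.n_samples)

    waveforms = segmentation.segment(record, config.segmentation)
    logger.info("segmentation: %d waveforms [%.2f s]",
                len(waveforms), time.perf_counter() - t0)

    pj, ijs = datasets.split_run(
        waveforms, record.sample_rate,
        pj_duration=config.pj_minutes * 60.0, ij_block_size=config.ij_block_size)
    logger.info("datasets: PJ of %d waveforms, %d IJ blocks",
                pj.n_waveforms, len(ijs))
    if not ijs:
        raise signal_io.ValidationError(
            "pipeline aborted at stage 'datasets': journey phase produced no "
            "complete IJ block")

    t1 = time.perf_counter()
    prof_kwargs = dict(d_max=config.d_max, folds=config.folds,
                       cv_scheme=config.cv_scheme, tie_tol=config.tie_tol)
    pj_profile = dop_model.profile(pj, seed=_profile_seed(config.seed, 0), **prof_kwargs)
    ij_profiles = [
        dop_model.profile(d, seed=_profile_seed(config.seed, d.index), **prof_kwargs)
        for d in ijs
    ]
    logger.info("profiling: %d datasets [%.2f s]",
                1 + len(ij_profiles), time.perf_counter() - t1)

    journey = decision.run_journey(
        pj_profile, ij_profiles, mode=config.mode, tolerance=config.tolerance,
        subject_id=record.subject_id, wrist=record.wrist.value)
    summary = analytics.summarize_cohort(
        {"PJ": [pj_profile], "IJ": ij_profiles}, journeys=[journey])

    result = PipelineResult(record=record, waveforms=waveforms, pj_dataset=pj,
                            ij_datasets=ijs, pj_profile=pj_profile,
                            ij_profiles=ij_profiles, journey=journey,
                            summary=summary)
    if outdir is not None:
        _persist(result, record, config, Path(outdir))
    logger.info("pipeline done: efficacy %.3f, terminal %s [%.2f s total]",
                journey.efficacy, journey.terminal_state.value,
                time.perf_counter() - t0)
    return result


def summary_to_dict(summary: analytics.CohortSummary) -> dict:
    return dataclasses.asdict(summary)


def _persist(result: PipelineResult, record, config: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    save_config(config, outdir / "config.yaml")
    signal_io.write_e4_bvp(record, outdir / "bvp.csv")
    segmentation.save_waveforms(result.waveforms, outdir / "waveforms.json",
                                sample_rate=record.sample_rate)
    datasets.save_datasets([result.pj_dataset] + result.ij_datasets,
                           outdir / "datasets.json")
    dop_model.save_profiles([result.pj_profile] + result.ij_profiles,
                            outdir / "profiles.json")
    decision.save_journey(result.journey, outdir / "journey.jsonl")
    (outdir / "summary.json").write_text(
        json.dumps(summary_to_dict(result.summary), sort_keys=True, indent=2),
        encoding="utf-8")


def run_cohort(
    config: RunConfig,
    n_subjects: int,
    wrists: tuple[str, ...] = ("left", "right"),
    outdir: Union[str, Path, None] = None,
) -> tuple[analytics.CohortSummary, list[decision.JourneyResult]]:
    """Simulate and analyze a synthetic cohort: one run per (subject, wrist),
    per-run seeds derived from ``config.seed``.

    Per-subject heart rate, jitter and artifact burden are drawn around the
    config's values so the cohort is heterogeneous, as a real study
    population would be.
    """
    pj_profiles, ij_profiles, journeys = [], [], []
    for s in range(n_subjects):
        subject_id = f"S{s + 1:02d}"
        for w_i, wrist in enumerate(wrists):
            run_seed = _profile_seed(config.seed, 1000 + s * len(wrists) + w_i)
            rng = np.random.default_rng(run_seed)
            sim = dataclasses.replace(
                config.simulation,
                hr_bpm=float(np.clip(rng.normal(config.simulation.hr_bpm, 8.0), 50, 110)),
                hrv_sd=float(abs(rng.normal(config.simulation.hrv_sd, 0.01))),
                artifact_rate=float(abs(rng.normal(config.simulation.artifact_rate, 1.0))),
                seed=run_seed,
            )
            record = synthetic.simulate_run(
                sim, config.sample_rate, pj_minutes=config.pj_minutes,
                journey_minutes=config.journey_minutes,
                subject_id=subject_id, wrist=signal_io.Wrist(wrist))
            run_cfg = dataclasses.replace(config, seed=run_seed, simulation=sim)
            run_out = Path(outdir) / f"{subject_id}_{wrist}" if outdir else None
            res = run_pipeline(run_cfg, record=record, outdir=run_out)
            pj_profiles.append(res.pj_profile)
            ij_profiles.extend(res.ij_profiles)
            journeys.append(res.journey)
    summary = analytics.summarize_cohort({"PJ": pj_profiles, "IJ": ij_profiles},
                                         journeys=journeys)
    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        (Path(outdir) / "cohort_summary.json").write_text(
            json.dumps(summary_to_dict(summary), sort_keys=True, indent=2),
            encoding="utf-8")
    return summary, journeys
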