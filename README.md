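# ppgram

Polynomial-regression remote automated monitoring of wrist
photoplethysmography (PPG) for autonomous hospital bed transport (AHBT).

## The problem

When a robotic hospital bed moves a low-risk patient between wards without a
nurse walking alongside, something must continuously answer one question: *is
the patient still in the state they were in when a nurse last checked?*
`ppgram` implements a deliberately simple, explicable monitoring algorithm
for that gate, built on a single feature of the wrist blood-volume-pulse
(BVP) signal:

1. **Pre-journey (PJ) reference.** A supervised 5-minute BVP measurement
   taken just before departure is segmented into individual cardiac pulse
   waveforms (trough-to-trough) — about 400 pulses at a nominal 80 bpm.
2. **In-journey (IJ) monitoring.** During transport, the latest
   non-overlapping block of 30 consecutive pulse waveforms forms an IJ
   dataset (N = 30 being the usual central-limit-theorem floor).
3. **Degree-of-polynomial (DoP) matching.** Each dataset is pooled into
   (tick, BVP) points on a shared per-pulse axis and fitted with polynomial
   regressions of degree *d* = 1..20. For each degree, k-fold cross-validation
   (k = 5) yields the **cross-validation score mean**

   CVSM(*d*) = (1/k) Σᵢ R²ᵢ(*d*),

   the mean held-out coefficient of determination over folds. The dataset's
   DoP is the smallest degree attaining the maximal CVSM. The bed may
   continue iff DoP(IJ) = DoP(PJ); a mismatch diverts it to the nearest stop
   point. **Efficacy** of a run is the fraction of positive matches over
   match attempts: 0 = never allowed to advance, 1 = journey completed.

No public recordings exist for this setting, so the package ships a
seed-deterministic synthetic wrist-PPG generator (jittered beat intervals,
two-Gaussian pulse morphology, baseline wander, sensor noise, motion-artifact
transients) and ground-truth polynomial fixtures that make every stage
testable end to end.

## Worked example

```python
from ppgram.pipeline import RunConfig, run_pipeline
from ppgram.synthetic import SimulationParams

cfg = RunConfig(seed=7, journey_minutes=10.0, simulation=SimulationParams(seed=7))
res = run_pipeline(cfg)
print(f"PJ: {res.pj_dataset.n_waveforms} waveforms -> DoP {res.pj_profile.selected_dop} "
      f"(CVSM {res.pj_profile.selected_cvsm:.3f})")
print(f"IJ: {len(res.ij_profiles)} datasets of 30 waveforms; "
      f"DoPs {[p.selected_dop for p in res.ij_profiles]}")
print(f"efficacy: {res.journey.efficacy:.3f}; terminal state: {res.journey.terminal_state.value}")
```

prints

```
PJ: 405 waveforms -> DoP 11 (CVSM 0.606)
IJ: 27 datasets of 30 waveforms; DoPs [8, 9, 9, 10, 9, 9, 11, 7, 8, 8, 8, 8, 7, 10, 8, 8, 7, 7, 16, 11, 8, 8, 8, 7, 8, 11, 9]
efficacy: 0.111; terminal state: exhausted
```

The simulated 5-minute reference window segments into 405 pulses and is best
modeled by an 11th-degree polynomial with CVSM 0.61 — held-out R² well below
1, as expected for a long window averaging over beat-to-beat variability.
The ten journey minutes yield 27 IJ blocks whose DoPs cluster around 8; only
3 of 27 equal the PJ DoP, so strict equality matching gives efficacy 0.111
and an offline evaluation that reaches the end of the stream (`exhausted`).
Low efficacy under free movement is the expected behavior of strict DoP
equality, not a failure of the pipeline.

The same pipeline is available from a shell:

```sh
ppgram simulate --duration 420 --seed 5 --out bvp.csv
ppgram segment --input bvp.csv --output waveforms.json
ppgram build-datasets --waveforms waveforms.json --pj-minutes 5 --ij-size 30 --output datasets.json
ppgram profile --datasets datasets.json --seed 3 --output profiles.json
ppgram decide --pj profiles.json --ij profiles.json --mode offline --output journey.jsonl
ppgram report --profiles profiles.json --journeys journey.jsonl --output report.json
```

`ppgram reproduce-synthetic --subjects 35 --outdir cohort/` simulates a full
two-wrist cohort and emits the cohort report (DoP histograms, CVSM spreads,
top/worst-5 CVSM panels, per-subject efficacy heatmap), clearly labeled
synthetic.

## Layout

| module | role |
| --- | --- |
| `ppgram.signal_io` | Empatica-E4-style BVP CSV read/write |
| `ppgram.segmentation` | trough-to-trough pulse segmentation |
| `ppgram.datasets` | PJ window / IJ block assembly |
| `ppgram.dop_model` | pooled polynomial CV scoring, DoP selection |
| `ppgram.decision` | equality matching, journey state machine, efficacy |
| `ppgram.analytics` | cohort histograms, CVSM spreads, extremes, plots |
| `ppgram.synthetic` | PPG simulator and ground-truth fixtures |
| `ppgram.pipeline` / `ppgram.cli` | end-to-end orchestration and CLI |

See `docs/methods.md` for the model, parameter choices, and limitations.
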