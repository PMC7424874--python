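# cuedmotion

Time-resolved decoding of motion direction from multi-sensor neural
recordings with an inverted encoding model (IEM), and the statistics needed
to ask when predictive cues modulate the decoded sensory representation.

The scientific setting: participants hear an auditory cue that predicts (at
60% validity) the likely direction — 27° or 63° — of an upcoming moving-dot
stimulus, while brain activity is recorded at 600 Hz from a few hundred
sensors. A decoder trained on task-irrelevant, full-coherence localizer
stimuli is applied to the cued task to track the represented direction
millisecond by millisecond, asking whether (and when) the cued direction
leaks into the sensory representation, and whether that neural effect
relates to the cue-induced bias in what people report seeing. Because such
datasets are rarely shared, the package includes a synthetic-data generator
that reproduces the experiment's statistical structure, so the entire
pipeline runs and is validated end to end against known ground truth.

## The model

The forward model expresses direction θ as amplitudes of 21 tuned channels,
f_i(θ) = max(0, cos(2π(θ−φ_i)/180))⁶, centers φ_i tiling [−45°, 135°).
Sensor data B (sensors × trials) follow B = W·C + N; W is fit by per-channel
least squares on localizer data. Inversion is noise-aware: per channel, the
residual covariance Σ_i is shrunk analytically (Ledoit–Wolf) toward ν_iI and
the spatial filter v_i = (Σ_i*)⁻¹w_i is normalized to v_iᵀw_i = 1. Channel
estimates Vᵀ·B of new data are turned into a decoded direction by taking the
argmax of the channel-weighted sum of tuning curves on a 0.1° grid. The
decoder runs in 28.3 ms windows stepped at 5 ms, is validated by
leave-one-run-out cross-validation on the localizer, trained finally at each
participant's 90–110 ms decoding peak, and applied across the whole cued
task. Group inference uses cluster-based permutation tests (sum-of-t mass,
10,000 sign-flip or label permutations), and brain–behavior links use
trialwise partial correlation controlling for the presented direction. See
`docs/methods.md` for the full account.

## Worked example

Simulate a 24-participant study in which the cued direction's sensor
pattern is reactivated at 135–180 ms, decode it, and test the cue effect:

```python
from cuedmotion.pipeline import detection_study_config, run_cohort

cohort = run_cohort(detection_study_config(n_perm=10000), master_seed=1)
for c in cohort.cue_effect_cluster.significant(0.05):
    print(f"cluster {c.start_ms:.0f}-{c.end_ms:.0f} ms, "
          f"mass={c.mass:.1f}, p={c.p:.4f}, d={c.d:.2f}")
print("bias split:", cohort.biased_mask.sum(), "attracted /",
      (~cohort.biased_mask).sum(), "not")
```

```
cluster 125-185 ms, mass=41.1, p=0.0001, d=1.01
bias split: 20 attracted / 4 not
```

The cluster test recovers (within the 28.3 ms smoothing window) the
135–180 ms interval in which the expectation template was injected. The
post hoc split recovers the attracted majority: 17 of 24 simulated
participants integrate the cue into their reports (expected bias +2°) and 7
are slightly repelled (−1.2°); at this run's trial counts report noise
flips a few of the repelled participants to a positive measured bias, which
is exactly the fragility such post hoc splits have in real data. The same pipeline is scripted
in `analysis/01_simulate_cohort.py` … `analysis/05_validation.py`, thin
drivers that write their tables to `results/`. A command-line interface
(`cuedmotion simulate | train-localizer | decode-main | stats | report`)
runs the stages on files (HDF5 epochs + TSV trial tables).

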