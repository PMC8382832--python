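# miniv1

Post-extraction analysis of one-photon microendoscopic calcium imaging of
primary visual cortex (V1): receptive-field mapping, orientation tuning,
population decoding of stimulus orientation, and probabilistic cross-session
cell tracking — plus a ground-truth synthetic-session generator used to
validate every stage.

## Who this is for

Labs recording V1 (or other visual areas) through implanted GRIN/prism
lenses with a miniscope while the animal fixates and oriented Gabor patches
flash in the periphery. The pipeline starts where source extraction (e.g.
CNMF-E) ends: it consumes ROI fluorescence traces (CSV, one column per ROI),
ROI spatial footprints (multi-page TIFF) and a trial table (CSV), and
produces tuning tables, decoding curves and cross-session registrations.
Raw-movie processing (motion correction, spatial filtering, source
extraction) is out of scope.

## The analysis

**Responses.** Traces are z-scored against the whole session, aligned to
stimulus onset at the native frame rate, and baseline-corrected by the mean
of the −500–0 ms pre-stimulus window per ROI and trial.

**Receptive field.** Stimuli sweep a 3 × 5 grid (eccentricities 5°/7°/9° ×
five clock azimuths). Per-trial 500–1500 ms mean responses are compared
across the 15 positions with the Tukey–Kramer test; the argmax position is
accepted as the receptive field only if it differs significantly from every
non-neighboring position (8-connected on the lattice).

**Orientation tuning.** An ROI is stimulus-responsive if, for any of the six
orientations θ ∈ {−90°, −60°, −30°, 0°, 30°, 60°}, the per-trial −1000–0 ms
baseline means differ from the 500–1500 ms response means (two-sided
two-sample t-test, Bonferroni α/6). With R(θ) the per-orientation peak of
the trial-averaged response (500–1500 ms), shifted so min R = 0:

    OSI = |Σθ R(θ) e^{i2θ}| / Σθ R(θ)

i.e. the resultant-vector length in the doubled angle (1 − circular
variance): 1 for a one-orientation responder, 0 for a flat curve. Because
some ROIs are suppressed by stimuli, the computation is repeated on −R and
the branch with the larger OSI wins. The preferred orientation is half the
resultant's argument, wrapped to [−90°, 90°).

**Decoding.** A multiclass ECOC model of binary linear SVMs (one-vs-one)
under stratified 10-fold cross-validation, with a 500-ms window sliding in
166-ms steps; each window is scored against a 100-repetition shuffled-label
null (two-sample t-test). ROI-count curves compare random ROI subsets with
selection by descending OSI.

**Cell tracking.** Fields of view are rigidly aligned; for every
cross-session ROI pair within 12 px, centroid distance and footprint
correlation feed a two-component mixture model (EM; lognormal distance ×
beta correlation margins). A pair's P_same is its posterior probability
under the "same cell" component; pairs with P_same ≥ 0.5 register greedily
one-to-one. Stability statistics follow: trace correlations vs shuffled
pairs, OSI correlation, and the 10°-binned preferred-orientation-difference
histogram with a 10,000-rep shuffle null and KS tests against uniform and
fitted-exponential references.

## Worked example

```python
import miniv1

# two synthetic sessions of the same field of view, one day apart
a = miniv1.make_session(n_cells=30, n_reps_per_condition=20, seed=1)
b = miniv1.derive_second_session(a, shift=(3, -2), rotation=1.0,
                                 centroid_jitter_sd=0.5, drop_fraction=0.25,
                                 add_count=5, tuning_drift_sd=5.0, seed=2)

tensor = miniv1.align_trials(miniv1.zscore_session(a.traces), a.trials)
tuning = miniv1.compute_tuning(tensor)
print(f"{tuning['responsive'].mean():.0%} of ROIs stimulus-responsive")
print(tuning[["responsive", "osi", "preferred_orientation"]].head(3))

result, model, _ = miniv1.track_sessions(a.footprints, b.footprints)
truth = b.correspondence
hits = sum(1 for x, y, _ in result.matches if truth.get(x) == y)
print(f"registered {len(result.matches)} pairs; "
      f"{hits}/{len(truth)} true pairs recovered")
```

prints:

```
100% of ROIs stimulus-responsive
        responsive       osi  preferred_orientation
roi_id
0             True  0.598912             -14.742536
1             True  0.738083             -34.155332
2             True  0.769753              24.735397
registered 22 pairs; 22/22 true pairs recovered
```

All 30 synthetic cells respond (they are built to), OSIs sit mid-range for
these moderate tuning concentrations, and every cell surviving the 25%
turnover is re-identified across the sessions with no false matches.

The same flow runs from the shell:

```sh
miniv1 run --out runs/demo --seed 1
miniv1 rf --tensor runs/demo/tensor_rf_session
miniv1 track --session-a runs/demo/session_a --session-b runs/demo/session_b \
             --out reg.json
```

Each `run` writes a manifest with the configuration, per-stage seeds and
SHA-256 checksums of every output, so identical seeds give bit-identical
runs.

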