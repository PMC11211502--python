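# gloveforge

A simulation-driven design toolkit for sensor-instrumented ("smart") gloves.
Designing a glove for gesture recognition normally means soldering sensors,
recording users, training a model, and repeating until the layout works.
`gloveforge` moves that loop into software: starting from hand key-point
trajectories (motion capture or monocular video estimators), it

1. **preprocesses** the noisy 21-key-point data onto a 26-DOF kinematic
   right-hand model (mirroring, per-segment rescaling, wrist translation,
   per-frame Kabsch rotation);
2. solves per-frame **inverse kinematics** into named joint-angle motion
   files, with quality diagnostics (mean distance error in mm, constraint
   violation ratio/magnitude) and take filtering;
3. **augments** the joint-angle dataset — hand sizes drawn from population
   statistics (length ~ N(19.3 cm, 1.25 cm), index:ring digit ratio
   ~ N(1.0, 0.05)) and key-pose time warping with bounded multiplicative
   noise u ~ U(−0.4, 0.4);
4. **synthesizes IMU readings** (specific-force accelerometer, gyroscope,
   magnetometer) at 15 candidate sensor sites from a = d²p/dt² and
   ω = 2 q\*⊗dq/dt, with a parametric error model (bias, noise density,
   misalignment, scale, saturation, quantization);
5. **ranks sensor placements** by joint-independence scores built from
   Pearson correlations of the joint-angle series x_{a,s,f,j}:
   inter-joint independence G_{f,j₁,j₂} = 1 − |r̄|, finger redundancy
   D_{f,a} = max_{f′≠f} |r̄|, inter-finger independence
   H_f = 1 − min_a D_{f,a}, and site importance I (products of G and H
   along each phalanx chain);
6. **evaluates designs**: 0.5 s sliding windows with 80 % overlap,
   leak-free 0.6/0.2/0.2 take-level splits, train-statistics
   normalization, training-time random rotation and multiplicative noise,
   and support-weighted F1 = Σ w_c · 2TP_c/(2TP_c+FP_c+FN_c) per candidate
   sensor set.

A synthetic-gesture module generates parametric vocabularies, forward
projects them to noisy markers, and builds labeled multi-subject
benchmarks, so the whole pipeline runs without any external dataset.

Audience: wearable/HCI researchers and engineers prototyping glove layouts,
and anyone needing simulated IMU data from articulated hand motion.

## Worked example

Rank sensor sites on a synthetic three-gesture vocabulary in which the thumb
and index finger act independently while middle/ring/pinky mirror each other
— so a correct ranking must put thumb/index sites on top:

```python
import numpy as np, gloveforge as gf

rng = np.random.default_rng(0)
ds = gf.make_pinch_dataset(rng)                      # 3 gestures x 6 sessions
scores = gf.importance_scores(ds)
print("top-3 sites:", scores.ranking[:3])
best, worst = gf.candidate_sets(scores, 3)

model = gf.default_model()
recs = gf.motions_to_recordings(ds, model, scores.ranking, gf.ImuErrorParams(), rng)
windows = gf.sliding_windows(recs)                   # 0.5 s windows, 80% overlap
windows.split = gf.split_takes(recs, seed=0)         # 0.6/0.2/0.2 by take
report = gf.design_report([best[-1]], windows, worst_sets=[worst[-1]], seed=0)
for row in report["results"]:
    print(f"{row['kind']:5s} {row['n_sensors']} sensors  weighted F1 = {row['weighted_f1']:.3f}")
```

prints

```
top-3 sites: ['INDEX_DISTAL', 'INDEX_MIDDLE', 'INDEX_PROXIMAL']
best  3 sensors  weighted F1 = 1.000
worst 3 sensors  weighted F1 = 0.291
```

The inter-finger independences behind the ranking are H ≈ 0.98/0.99 for
thumb/index and H = 0 for the three mutually redundant fingers: a classifier
on the three most important sites separates the gestures perfectly, while
the three least important sites carry almost no class information.

The same flow is scriptable from a shell:

```bash
gloveforge synth --out takes --subjects 2 --takes 3 --seed 0
gloveforge rank takes --out rank.json
gloveforge report takes --out report.json --k 3 --seed 0
```

plus `gloveforge preprocess`, `ik`, `augment`, and `simulate` for the
marker-to-motion-to-sensor stages. See `docs/methods.md` for the model,
conventions, and limitations.

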