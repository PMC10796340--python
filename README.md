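# spastigen

Synthetic data generation for upper-limb spasticity modelling: a
desk-scale simulator that builds a demographically varied virtual patient
cohort, synthesizes parameterised upper-limb movements as 3D marker
trajectories, and forward-simulates muscle-level spastic behaviour across
the six grades of the Modified Ashworth Scale (MAS).

## Who this is for

Researchers in neurorehabilitation and musculoskeletal simulation who need
*heterogeneous, labelled* motion and muscle-state data — for example to
prototype spasticity classifiers or instrumented-assessment pipelines —
where real patient recordings are scarce. Everything is generated from
code and packaged reference tables; no external data is required.

## The model

**Cohort.** 92 virtual individuals spanning 4 phenotypes × 2 sexes × 3
adult ages (23, 48, 68; plus two Latino individuals at 33), with
body-shape ("mass") and muscle-tone slider percentages in {25, 50, 75}.
Each record carries stature and right upper-limb segment lengths
(upper arm, forearm, hand, cm).

**Movements.** Four clinically standard right upper-limb movements, each a
6 s round trip sampled at 100 Hz (601 frames) with the full range of
motion reached at 3 s: elbow flexion–extension (140°), shoulder
flexion–extension (90°), shoulder abduction–adduction (90°) and forearm
pronation–supination (150°, swept −75°→+75° about neutral). Keyframes are
joined by the minimum-jerk quintic

&nbsp;&nbsp;&nbsp;&nbsp; x(s) = x₀ + Δx·(10s³ − 15s⁴ + 6s⁵),

the standard analytic model of point-to-point human reaching (zero
velocity and acceleration at every keyframe).

**Skeleton and markers.** A 71-joint skeleton (6 per lower limb, 24 per
upper limb, 11 core/head/neck) scaled to each patient; forward kinematics
of the right arm chain produces marker trajectories, reduced to the 14
markers a musculoskeletal model needs, rotated −90° about the vertical
axis into model coordinates, and written as TRC (mm).

**Spastic muscle.** A rigid-tendon Hill-type muscle: force =
f_max·(a·f_L(l̃)·f_V(ṽ) + f_P(l̃))·cos α, with a Gaussian active
force–length curve, a Hill force–velocity hyperbola with an eccentric
plateau, an exponential passive element, and first-order
excitation→activation dynamics (τ_act = 10 ms, τ_deact = 40 ms).
Spasticity is a delayed velocity-feedback stretch reflex

&nbsp;&nbsp;&nbsp;&nbsp; e_sp(t) = clip( G · max(0, ṽ(t−d) − v_th), 0, 1 ),

where ṽ is normalized fiber lengthening velocity (optimal lengths/s),
G the gain, v_th the threshold and d = 30 ms the neural delay. The six MAS
grades map to strictly increasing gains (0 … 8) and strictly decreasing
thresholds (∞ … 0.02), so higher grades fire earlier and harder when the
muscle is stretched. Per movement, the recruited muscles follow a
motion–muscle table (e.g. elbow flexion–extension → BICLong, BICShort,
BRA); constant moment arms make every musculotendon length analytic:
l_mt(θ) = l_mt,0 − r·θ.

## Worked example

```bash
python examples/03_spastic_simulation.py
```

prints (patient 1, elbow flexion–extension, brachialis):

```
  MAS  0: peak reflex excitation 0.000, reflex active 0.00 s, peak activation 0.000, peak force   103.2 N (BRA)
  MAS  1: peak reflex excitation 0.078, reflex active 1.49 s, peak activation 0.078, peak force   103.2 N (BRA)
  MAS 1+: peak reflex excitation 0.205, reflex active 1.77 s, peak activation 0.205, peak force   217.7 N (BRA)
  MAS  2: peak reflex excitation 0.510, reflex active 2.05 s, peak activation 0.510, peak force   541.6 N (BRA)
  MAS  3: peak reflex excitation 1.000, reflex active 2.37 s, peak activation 1.000, peak force  1068.6 N (BRA)
  MAS  4: peak reflex excitation 1.000, reflex active 2.63 s, peak activation 1.000, peak force  1068.6 N (BRA)
```

The elbow flexors lengthen during the return phase, so the reflex fires in
the second half of the movement; with grade the reflex grows stronger
(peak excitation) and starts earlier (active duration), saturating at the
highest grades — grade 0 stays purely passive. The other examples cover
the cohort (`01`), movement synthesis and TRC export (`02`), inverse
kinematics (`04`) and dataset generation with manifest verification
(`05`).

A thin CLI wraps the same library calls:

```bash
spastigen cohort --out cohort.csv
spastigen motion --patient 1 --movement elbow_flexion_extension --out elbow.trc
spastigen simulate --patient 1 --movement elbow_flexion_extension --grade 1+ --out elbow.sto
spastigen dataset --out dataset/ --patients 1..2 --seed 7
```

## Dataset layout

A full default run (`spastigen dataset --out DIR`) produces
92 × 4 = 368 TRC motion files and 368 × 6 = 2,208 STO simulation bundles:

```
DIR/
  cohort/cohort.csv
  motions_trc/patient_001/elbow_flexion_extension.trc   ...
  simulations_sto/patient_001/elbow_flexion_extension/grade_0.sto ... grade_4.sto
  manifest.csv            # per-file content hashes, seed, config hash
```

Runs are byte-reproducible given seed and config; `verify_dataset`
re-hashes and re-parses the tree.

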