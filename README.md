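# motordcm

Effective-connectivity analysis of the cortical motor network during
metronome-paced sequential finger tapping, built for studying motor-circuit
changes across the Huntington's disease spectrum (healthy controls,
pre-symptomatic and early-manifest carriers of the expanded huntingtin CAG
repeat).

The package implements the full analysis chain as a tested library:

* **Paradigm** — the 6-condition tapping block design (simple/complex
  sequences × 0.5/1.5 Hz pacing × auditory rest), with model inputs on a
  microtime grid.
* **Generative model** — deterministic bilinear one-state dynamic causal
  model, `dz/dt = (A + Σ u_j B_j) z + C u`, over seven regions (pSMA, cSMA,
  lM1, lPMd, rPMd, lSPC, rSPC), coupled to a Balloon–Windkessel hemodynamic
  forward model and integrated by a batched RK4 kernel.
* **Inversion** — variational Laplace (Gauss–Newton with
  Levenberg–Marquardt damping, per-region noise precisions, discrete-cosine
  drift confounds with a 152-s cutoff), with the ≥ 10% variance-explained
  quality check.
* **Post-hoc reduction** — analytic Savage–Dickey log evidence for nested
  prior reductions and a greedy backward search for the winning model.
* **Behavior** — cue–response timing inaccuracy, sequence-aware accuracy
  and mistake rules, exclusion flags, and the disease burden score
  DBS = age × (CAG − 35.5).
* **Synthetic cohort** — a 77/62/16 cohort with the reported covariate
  distributions, group-dependent modulatory couplings (the lSPC→lPMd
  complexity effect flips sign between preHD and earlyHD), a planted
  9-carrier sub-cluster, a putamen-volume/coupling correlation, BOLD at a
  controlled SNR, and press logs with group-dependent timing jitter.
* **Group statistics** — connection-wise ANCOVA (extra sum of squares over
  group dummies, Bonferroni over 30 intrinsic + 17 modulatory couplings),
  pairwise post-hoc contrasts, Pearson partial correlations.
* **Clustering** — Ward linkage with squared-Euclidean proximity, an
  SPSS-style agglomeration schedule, scree-based selection of the cluster
  count, and carrier sub-group assignment.

No real study data are required (or included): the synthetic cohort makes
every downstream stage testable end to end. `docs/methods.md` documents the
models, defaults, and what the generator does and does not emulate.

## Worked example

Generate a small synthetic cohort, invert one pre-symptomatic carrier's
model, and read off the key coupling:

```python
import numpy as np
from motordcm import build_paradigm, winning_model_preset, default_priors, invert
from motordcm.cohort import CohortSpec, PlantedCluster, generate_cohort
from motordcm.behavior import score_log

design = build_paradigm(seed=42)
net = winning_model_preset()
spec = CohortSpec(n_per_group=(2, 2, 2), planted_cluster=PlantedCluster(size=1), seed=42)
subjects = generate_cohort(spec, design=design, network=net)

sub = subjects[3]  # a pre-symptomatic carrier
priors = default_priors(net)
post, diag = invert(sub.timeseries, design, net, priors, dt=1.5, max_iter=24)
k = priors.packing.labels.index("B:complexity:lPMd<-lSPC")
print(f"variance explained: {diag.variance_explained:.2f}  passed QC: {diag.passed_qc}")
print(f"lSPC->lPMd complexity coupling: true {sub.params.B['complexity'][3,5]:+.2f} Hz, "
      f"estimated {post.mean[k]:+.2f} +/- {np.sqrt(post.cov[k,k]):.2f} Hz")
scores, summary = score_log(sub.press_log)
print(f"tapping accuracy: {summary.overall_accuracy:.1f}%  "
      f"timing SD: {summary.per_condition.sd_inaccuracy.mean()*1000:.0f} ms")
```

Output:

```
variance explained: 0.47  passed QC: True
lSPC->lPMd complexity coupling: true -0.86 Hz, estimated -0.65 +/- 0.11 Hz
tapping accuracy: 97.0%  timing SD: 96 ms
```

This subject belongs to the planted sub-cluster, so its complexity
modulation of the parietal→premotor coupling is strongly inhibitory
(−0.3 Hz group mean plus the −0.4 Hz sub-cluster offset); the inversion
recovers it within two posterior standard deviations at the default
signal-to-noise level, and the behavioral scores show intact tapping with
~100 ms timing variability.

The same analysis runs from the shell:

```sh
motordcm run --seed 7 --n-per-group 15 15 15 --out runs/demo
motordcm synth --seed 7 --n-per-group 4 4 4 --out cohort/
```

`run` writes per-stage tables (`parameters.csv`, `ancova.csv`,
`clusters.csv`, `correlations.csv`, …) plus a `manifest.json` recording the
seed, option/input hashes and per-stage subject counts; re-running the same
configuration reproduces every table byte for byte.

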