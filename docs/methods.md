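# Methods

`xbrainage` implements an explainable brain-age analysis as a fully
testable pipeline on synthetic phantoms. This note records the models,
the generator, the numerical choices, and what the phantom experiments
do and do not demonstrate about real data.

## The analysis

**Brain age and BrainAGE.** A regression network predicts a subject's
age from a 3-D image; BrainAGE is the gap `predicted − chronological`
in years. Because regression to the mean makes such models overestimate
young and underestimate old subjects, the raw gap is corrected by
fitting `gap ~ alpha·age + beta` (OLS) on a dedicated held-out
correction cohort and subtracting the fit everywhere else (the
offset-style linear correction). The correction coefficients are never
refitted on evaluation data, and the correction set never overlaps the
training, selection, or clinical sets.

**Transfer learning.** Each modality channel gets its own model pair: a
3-D convolutional autoencoder (CAE) trained to reconstruct volumes (MSE
loss), whose encoder is then copied into the age regressor and frozen;
only the freshly initialized dense head trains on (volume, age) pairs.
Model selection keeps the checkpoint with the best validation score
(reconstruction MSE for the CAE, age MAE for the regressor) within the
last `selection_window` epochs (default 30), ties going to the earliest
epoch in the window.

**Architecture.** The encoder is B stride-2 convolution blocks (3³
kernels, ReLU), a flatten, and a dense latent; the decoder mirrors it
with stride-2 transposed convolutions; the regression head is dense
layers ending in one scalar. Defaults for 32³ inputs: widths (8, 16,
32), latent 64, head (32,). The network engine is written on NumPy in
float64 with exact reverse-mode gradients for parameters *and inputs*;
the input gradient is the saliency primitive. Everything is
single-threaded and seed-deterministic, so "deterministic mode" is the
only mode; identical seeds give bit-identical runs.

**Sensitivity maps.** The vanilla map is the gradient of the predicted
age with respect to every input voxel. SmoothGrad averages the gradient
over `n_samples` (default 25) Gaussian-perturbed copies of the input,
`sigma = noise_level · R`. The noise level is calibrated per modality on
the correction cohort: for each grid level (0 % to 50 % in 2 % steps, 26
levels) the maps are parcellated and each region's mean sensitivity is
Pearson-correlated with age; the level maximizing the mean |r| over
regions wins, ties to the smallest level. Maps are always computed from
the *uncorrected* model output — the bias correction lives entirely in
the prediction table and never touches the gradient path.

**The sigma reference R.** For a single volume, R defaults to that
volume's dynamic range (max − min), the usual SmoothGrad convention.
For cohort analyses the pipeline instead fixes R per modality as the
median dynamic range of the calibration cohort. The per-volume
convention is subtly wrong in a cohort setting: any process that shifts
a subject's intensity range — ageing, pathology — then also scales that
subject's noise amplitude, and the changed smoothing leaks into every
region of the map as a coherent spurious group/age signal. On the
default phantom the per-volume ranges of patients and controls differ
by ~28 % (t ≈ 8.5), and switching to a fixed per-modality reference
roughly tripled the morphometry/sensitivity condition-set Jaccard. A
fixed reference per input type is also what a per-modality noise choice
means operationally.

**ROI statistics (stage 1).** Each map (morphometric channel or
sensitivity map) is reduced to per-region means over an integer atlas
(background 0 excluded). Every region is tested with an ANCOVA — the
clinical condition as the group factor, age as a covariate — and the
per-factor p-vectors are Benjamini–Hochberg FDR-corrected across
regions. The FDR family is one (map type × modality × factor)
combination; families are never pooled across factors or modalities.
Significance means q < alpha (default 0.05, strict). Empty atlas
regions raise instead of yielding NaN, because silently missing regions
would corrupt the stage-2 set denominators.

**ANCOVA details.** The general linear model is assembled explicitly:
intercept, treatment-coded condition, continuous age, optionally
treatment-coded sex; no interactions. Sums of squares are Type II via
the drop-one construction (equal to Type III here, with no
interactions); partial eta squared is SS_effect/(SS_effect +
SS_residual). The BrainAGE ANCOVA controls for age and sex and is run
on both corrected and uncorrected gaps; the stage-1 ROI ANCOVA controls
for age only (sex available via a flag). The implementation is
vectorized over regions — one least-squares solve per design for all
regions at once — which is what makes per-ROI testing and the
calibration simulations cheap; `pingouin.ancova` serves as an
independent cross-check in the test suite.

**Concordance (stage 2).** For each modality and factor, the Jaccard
index |A∩B|/|A∪B| compares the significant-region sets from the
morphometric and sensitivity analyses. Two empty sets give Jaccard 0 by
arithmetic convention, yet the analyses then agree perfectly; the
report therefore carries a `both_empty` flag and a whole-universe
status-agreement fraction (1.0 for two empty sets) so that perfect null
agreement stays machine-readable.

## The phantom generator

Per voxel of region r in channel c:

    value = mixing[c] · ( baseline[r]
                          + age_slope[r] · (age − age_ref)
                          + disease_offset[r] · 1[patient]
                          + subject_intercept
                          + region_intercept[r] )   + N(0, voxel_sd)

* **Atlas** — K ellipsoidal regions seeded on a jittered lattice inside
  the grid; contested voxels go to the nearest region center (ties to
  the lowest label), uncontested voxels outside every ellipsoid are
  background. Defaults: 32³ grid, K = 24. Deterministic per seed;
  labels are disjoint by construction and every region is non-empty.
* **Ages** — i.i.d. uniform on [18, 88] years, the adult range the
  cohort tables of such studies span; sex is balanced Bernoulli(0.5)
  and has no effect on voxel values by default, so the sex covariate is
  exercised under the null.
* **Age slopes** — heterogeneous magnitudes of 0.4–1.2 % of baseline
  per year; 75 % of regions decline (grey/white-matter-like atrophy)
  and 25 % grow (CSF/ventricle-like expansion). The mixed signs matter:
  they keep the age direction in region space distinguishable from the
  uniform direction spanned by the global subject intercept. With
  all-negative near-uniform slopes the two are nearly collinear, the
  model's region-wise weights become underdetermined, and a localized
  disease shift projects onto an essentially arbitrary direction.
* **Disease effect** — `disease_extra_years` (default 40 y) of
  additional ageing applied along each disease region's own slope, for
  6 designated regions. Patients therefore look older exactly where the
  pathology lives, in whichever tissue direction that region ages.
* **Noise** — a global per-subject intercept (SD 0.05 units,
  scanner/biology), a per-(subject, region) intercept (SD 0.03 units,
  region-specific individual variability), and i.i.d. voxel noise (SD
  0.05). The region-level term is essential: without it all regions are
  perfectly collinear given age and the inverse problem the network
  solves has no region-wise structure to recover.
* **Channels** — modalities are emulated by scalar mixing of the single
  latent atrophy field (weights 1.0, 0.7, …). This preserves the
  per-modality analysis structure without modelling segmentation.
* **Determinism** — every subject's random effects and noise come from
  a stream keyed by (dataset seed, subject id), so any volume can be
  re-rendered bit-exactly from the manifest.

**What the phantom does not emulate:** anatomy, registration error,
multi-site scanner effects, longitudinal change, nonlinear ageing
trajectories, or spatially correlated noise. Passing tests therefore
demonstrate that the pipeline's statistics and wiring are correct and
that the method recovers known effects under a favourable
signal-to-noise regime — not that it would do so on real MRI.

## Cohort roles and problem sizes

The default experiment uses 300 subjects split into disjoint roles
mirroring the multi-dataset design such studies use: 60 pretraining
(CAE, with a 10 % reconstruction-validation split), 100 regressor
training, 20 checkpoint selection, 40 bias correction and noise
calibration (controls only, like the held-out site such studies
reserve), and 80 clinical evaluation (40 patients / 40 controls). The
32³ grid and the short schedules (CAE 12 epochs, regressor 40 epochs,
batch 16) are desk-scale choices that keep a full two-modality
experiment in a few CPU-minutes while leaving the analysis structure
intact; every size is configurable.

## Numerical choices

* Optimizer: Adam. CAE lr 1e-3; regressor head lr 1e-2 with the output
  bias initialized to the training-set mean age (the head otherwise
  spends most of its budget shifting the output scale from 0 to ~50
  years). Selection windows: 8 of 12 CAE epochs, 30 of 40 regressor
  epochs.
* Checkpoint snapshots are kept in a ring buffer covering only the
  selection window, bounding memory.
* Saliency: default signed maps (absolute mode available); calibration
  uses 8 SmoothGrad samples on up to 20 calibration subjects per level
  (26 levels), final clinical maps use 25 samples. Degenerate Pearson
  correlations (zero-variance ROI sensitivity) count as r = 0.
* BH-FDR is computed by statsmodels; significance is q < alpha
  (strict), matching the package's set semantics downstream.
* ReLU subgradient at exactly 0 is 0. Finite-difference checks of the
  engine avoid the measure-zero kink configurations an untrained
  zero-bias network exhibits.
* Jaccard(∅, ∅) = 0 with `both_empty = True`; `status_agreement` = 1.

## Known limitations

* The phantom's linear-in-age signal makes age regression easier than
  on real MRI; reported MAEs (~1–2 y) are not comparable to real-data
  MAEs.
* Sensitivity-map group differences exhibit cross-talk: a localized
  input shift changes the gradient field globally through the shared
  nonlinear features, so localization of disease regions by sensitivity
  differences is noisier than by morphometry — visible in the default
  experiment, where the morphometric analysis recovers all six disease
  regions and the sensitivity top-6 ranking typically recovers four or
  five.
* One noise level is chosen per modality (globally over ROIs), and the
  aggregate calibration score (mean |r|) is one of several defensible
  choices; the per-ROI correlation table is retained in the report so
  alternatives can be audited.
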