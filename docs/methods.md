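# Methods

## The problem

Some patients with anti-LGI1 autoimmune encephalitis show clear FDG-PET
metabolic abnormality in the medial temporal lobe and basal ganglia
("completely detectable", CD), while in others the same disease process
is too weak to be seen by eye ("non-CD"). The package implements a
cross-decoding strategy for this setting: learn the metabolic pattern
where it is strong (CD patients vs. healthy controls), then test whether
the same pattern separates the weak cohort (non-CD patients vs. a second
control group) that never touched the training step. Success on the held
-out cohort is evidence that the two cohorts share the same underlying
pattern of signal change.

## Model

Preprocessed, vectorized PET images form a subjects x voxels matrix X.
Spatial ICA models X = A·S: rows of S are statistically independent
spatial sources (disease pattern, other brain activity, noise,
background), and A holds subject-specific mixing coefficients. The
coefficients, not the voxels, are the classifier features — a drastic
and structured dimensionality reduction (V ~ 10^4-10^5 voxels down to
k <= n_subjects components).

### Preprocessing

Volumes (assumed already co-registered to a common space) are:

1. resampled to an isotropic grid (default 2 mm, trilinear);
2. smoothed with an isotropic Gaussian (default 8 mm FWHM;
   sigma = FWHM / (2 sqrt(2 ln 2)) per axis in voxel units; nearest
   boundary extension so constant images are preserved);
3. intensity-normalized: each voxel is divided by the mean of the
   brightest ceil(0.2·m) voxels among the m voxels strictly exceeding
   one-eighth of the whole-volume mean. The count rounding (ceil,
   minimum one) and the whole-volume mean are our choices where the
   convention is underdetermined; both guarantee a nonempty reference
   set and make the operation invariant to positive rescaling;
4. masked to gray matter and vectorized in x-fastest (Fortran) scan
   order, which is fixed so coefficient matrices are portable.

### Reliability-clustered ICA

Fixed-point (FastICA) estimates depend on their random initialization,
so a single run is not trustworthy with n ~ 34 subjects. We use the
repeat-and-cluster construction: the training matrix is voxel-wise
centered and PCA-whitened once; symmetric fixed-point ICA with the
logcosh contrast is run `n_runs` times (default 200; the reference
phantom experiments use 20) from seeded random rotations on that shared
whitening; all resulting component images are pooled and clustered by
absolute Pearson correlation (average linkage, cut at k clusters); each
cluster is summarized by its centrotype, the member with the highest
mean similarity to the rest of its cluster, and that mean similarity is
reported as the cluster quality (values below 0.8 are surfaced as
warnings). Similarity is taken as |r| because component sign is not
identified. Per-run seeds derive from the master seed through
`SeedSequence([master, run_index])`.

Voxel-wise centering removes one degree of freedom across subjects, so
at most n_subjects - 1 components are estimable; `decompose` checks the
rank of the centered matrix and errors with advice when the requested
order exceeds it. The component count therefore defaults to the number
of training subjects only nominally; practical runs pass an explicit
smaller order (the reference phantom runs use 16).

### Cross-cohort projection and normalization

Centrotype components are standardized to zero mean / unit variance over
voxels. Any cohort is projected into the coefficient space via the
Moore-Penrose pseudoinverse (SVD with relative cutoff 1e-10):
A = (X - mean_train) · S⁺. Test images are centered with the *training*
voxel means — the projection must not adapt to the test cohort.
Coefficient columns are then standardized using the training mean and
training sample SD (n-1 denominator); the same statistics are applied to
the test matrix.

### Classifier and hyperparameter selection

The classifier is logistic regression minimizing

    mean negative log-likelihood + (lambda / 2) ||w||^2

with an unpenalized intercept, fit by damped Newton iterations with
backtracking to a gradient infinity-norm of 1e-8 (the objective is
strictly convex in w, so the fit is deterministic and seed-free). In
the common scikit-learn convention this lambda corresponds to
C = 1 / (n·lambda).

lambda is selected from the 21-value grid 2^-10 ... 2^10 by leave-one-out
cross-validation: for each candidate, each training sample is held out
once and its predicted probability recorded; a single AUC is computed on
the n pooled held-out probabilities (per-fold AUC is undefined for
singleton folds). The candidate with the highest pooled AUC wins; ties
break toward the smallest lambda. On comfortably separable training data
every small lambda reaches AUC 1.0 and the grid minimum 2^-10 is
returned.

Labels are 1 = patient, 0 = healthy; a subject is called a patient when
its predicted probability strictly exceeds 0.5 (probability exactly 0.5
is called healthy). Reported metrics: accuracy, sensitivity (patient
recall), specificity (control recall), the full ROC over all distinct
probability thresholds, and trapezoidal AUC.

### Component maps

Components are ranked by |weight| in the final classifier; the top
ceil(top_fraction·k) are selected (5% of 34 components = 2). Each
selected component image is multiplied by the sign of its weight, so
positive map values always mean relative hypermetabolism in patients,
then standardized to a z-map over mask voxels. Suprathreshold voxels
(|z| > 2.58, the two-sided 1% normal critical value) are grouped into
connected clusters — positive and negative exceedances separately, never
merged across sign — under 18-connectivity by default (6 and 26
selectable); clusters with extent below 50 voxels are discarded. Local
peaks (voxels whose |z| is maximal within their neighborhood) are
reported in mm; peaks within 8 mm of a stronger peak in the same cluster
are suppressed (the separation radius is a documented choice, not a
published convention). Optional anatomical annotation reads a
user-supplied label volume and name map; no atlas is bundled.

### Demographic comparisons

Continuous variables use the pooled-variance (Student) two-sample t-test
with df = n1 + n2 - 2, computable from group summaries (n, mean, sample
SD) — the pooled form is what the published degrees of freedom imply.
Categorical variables use Fisher's exact test, two-sided by the
point-probability convention (sum of hypergeometric probabilities of all
same-margin tables no more likely than the observed one). The test suite
checks this against exhaustive integer-arithmetic enumeration for every
2x2 table with total at most 40.

## The phantom generator

Because no patient imaging is distributed, the package ships a seeded
generator whose defaults define the reference study conditions:

- **Geometry.** 40 x 48 x 40 grid at 2 mm, mask = an ellipsoid with
  semi-axes 90% of each half-extent minus an 8 mm central
  "ventricle" sphere (29,120 voxels); a reduced 24 x 28 x 24 preset
  serves quick experiments.
- **Sources.** Four disease blobs — two medial-temporal-like
  (center (±24, -8, -16) mm, radius 8 mm) and two basal-ganglia-like
  ((±14, 6, 0) mm, radius 7 mm) — as isotropic Gaussians with
  FWHM = radius truncated at 3 sigma, plus 6 confound fields (white
  noise smoothed with the same 8 mm kernel as preprocessing, so their
  spatial autocorrelation resembles real components). All sources are
  standardized over the mask.
- **Subjects.** volume = baseline (constant 100 in-mask; the later
  intensity normalization removes scale) + sum of loading·source +
  i.i.d. Gaussian voxel noise (SD 0.5), clipped at zero (PET
  nonnegativity; effectively inactive at the default amplitudes).
  Disease loadings are N(mu_cohort, 0.25) with mu = 0.8 (CD), 0.55
  (non-CD), 0 (healthy); confound loadings are N(0, 1) for everyone.
- **Design.** Cohort sizes (17, 16, 17, 16); CD + first healthy group =
  training split, non-CD + second healthy group = testing split,
  overridable in the sheet.

The non-CD mean is deliberately above the CD/healthy midpoint: a
cross-trained classifier's 0.5 boundary falls near that midpoint, so a
weak cohort at exactly half the training amplitude would be undetectable
at the fixed threshold by construction, regardless of AUC. 0.55 makes
the scenario solvable but not trivial (reference results: median test
specificity 1.0, sensitivity ~0.8-0.9, the same regime as the real
study).

What the phantom does **not** emulate: scanner physics (attenuation,
PSF anisotropy, partial-volume effects), anatomical variability,
registration error, age/sex effects on metabolism, and non-Gaussian
noise. Passing phantom tests therefore demonstrates the pipeline's
correctness and statistical calibration under the stated generative
model, not clinical performance.

## Reference experiment sizes

- Recovery experiment: 10 seeds, full-size phantom, 16 components,
  20 ICA runs per seed (~15 s per seed on one CPU core).
- Null calibration: 20 seeds on the reduced preset with all disease
  loading means zero; mean test accuracy is compared to chance within
  three standard errors.
- Unit/property tests run on toys of at most a few hundred voxels.

## Numerical choices and degenerate inputs

- Pseudoinverse: SVD cutoff 1e-10 relative to the largest singular value.
- Newton fit: damped with Armijo backtracking; non-convergence within
  200 iterations raises, reporting the achieved gradient norm.
- Ties: lambda ties -> smallest lambda; |weight| ties -> smaller
  component id; equal-|z| plateau in a cluster -> the first argmax voxel.
- Errors are raised for: all-zero images in intensity normalization,
  zero-SD coefficient columns (named), zero-weight sign correction,
  zero in-mask SD z-maps, single-class LOOCV folds, rank-deficient
  decomposition requests.
- Connected-component labeling and smoothing delegate to scipy.ndimage;
  ICA runs delegate to scikit-learn's fastica on the package's own
  shared whitening.

## Known limitations

- LOOCV-pooled AUC is an optimistic but standard small-sample selector;
  no nested CV is attempted (out of scope).
- The exact ICA dialect (similarity metric and linkage) of other
  implementations varies; ours (|Pearson r|, average linkage) is
  documented rather than asserted as identical to any toolbox.
- Whether test images should be centered with training or test voxel
  means is underdetermined in the cross-decoding literature; training
  means are used here to keep the firewall strict.
- Region annotation depends entirely on the user-supplied label volume.
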