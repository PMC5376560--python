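# Methods

## Scientific setting

Masticatory performance — how well a person chews — declines in later life,
and part of that decline is thought to reflect the brain's sensorimotor
control of chewing rather than peripheral oral factors alone.  The analysis
implemented here relates a behavioral chewing score to resting-state
functional connectivity (FC) over a fixed set of mastication-related brain
regions: 12 bilateral regions of interest (primary motor cortex M1,
premotor cortex PMC, primary/secondary somatosensory cortices S1/S2,
superior parietal lobe SPL, anterior insula aINS, dorsal anterior cingulate
dACC, caudate CaN, thalamus THA, and cerebellar subdivisions CAnt, CPost67,
CPost8), i.e. 24 nodes and 276 unique edges.

The behavioral score is the masticatory performance index (MPI): after a
subject chews a color-changeable gum, the MPI is the color change ΔE of the
gum in CIE L\*a\*b\* space.  `compute_delta_e` implements the CIE76 form
ΔE = √(ΔL² + Δa² + Δb²); perceptually weighted variants (CIE94, CIEDE2000)
are deliberately not supported, and the CIE76 choice is a documented
simplification since the assessment protocol does not pin down a variant.

## Pipeline

For each subject, regional mean BOLD-like time series (183 timepoints,
TR = 2 s by default) pass through a fixed chain:

1. **Discard** the first 3 volumes (saturation transient).
2. **Linear detrend** each node signal (degree-1 least squares; the output
   has exactly zero trend and zero mean).
3. **Bandpass 0.01–0.08 Hz** with an ideal rectangular discrete-Fourier
   filter: coefficients with frequency in the closed band are kept, all
   others (including DC) zeroed.  This mirrors the behavior of the widely
   used resting-state toolkits, is exactly idempotent, and has unit in-band
   and zero out-of-band transfer at on-grid frequencies — which makes it
   exactly testable.  Band edges are inclusive.
4. **Nuisance regression**: OLS residualization on an intercept plus the
   six rigid-body motion parameters and (when available) ventricle and
   deep-white-matter mean signals.  The whole-brain global signal is *not*
   regressed.  Regressors are used as supplied — they are not themselves
   band-filtered by default; a caller can filter them first if desired.
   Constant regressors (e.g. a motionless trace) are collinear with the
   intercept and are dropped rather than failing the subject.

The chain order is enforced: every `ROITimeSeries` carries a `stage` tag and
each operation refuses inputs at the wrong stage.  Calling the filter on an
already-filtered series is allowed (idempotence), everything else out of
order is an error.

**Connectivity.**  Edge (i, j) is the Pearson correlation r between the
preprocessed node signals, mapped to the weight |atanh r| (Fisher's
variance-stabilizing transform, absolute value), so anticorrelation counts
as strength.  |r| ≥ 1 between distinct nodes is a hard error by default; an
explicit `clip=True` truncates at 1 − 1e−7 (real data never reaches the
boundary; degenerate synthetic inputs can).  Degree centrality (DC) of a
node is the sum of its 23 incident weights; high-DC nodes are hubs.

**Statistics.**  Hub identification and edge screening use the partial
correlation of DC (or edge weight) with MPI controlling age and a 0/1
gender indicator (F=0, M=1): both variables are residualized on
[intercept | covariates], r is the Pearson correlation of the residuals,
t = r√(df/(1−r²)) with df = n − 2 − k, two-tailed p.  A node is a hub iff
r_partial > 0 *and* p < α (α = 0.05, uncorrected — the analysis is
exploratory by design and applies no multiplicity adjustment; edge
screening reports signed r_partial with no positivity filter).  Group
analyses run strictly within the older/younger subgroups; no pooled
between-group FC contrast is computed, mirroring the design being
reproduced (age-related anatomy and motion differences would confound it).

Demographics use a Welch t test by default (the emulated groups have
clearly unequal MPI variances; a pooled mode is provided), a Yates
continuity-corrected χ² for the 2×2 gender table with the |O−E|−0.5 term
clamped at zero (so perfectly balanced tables give exactly χ² = 0), and
t-based two-tailed Pearson correlation tests for the age–MPI decline.

**Median split.**  The cohort is split at the median age.  For even n the
threshold is the usual midpoint of the two central ages; for odd n (which
arises when motion exclusion removes a subject) it is the midpoint of the
two ages just below and at the centre, so the middle subject joins the
older group and the halves differ by at most one.  A subject whose age
equals the threshold is a hard error with an explicit tie report — silent
tie-breaking would make group membership arbitrary.

**Motion QC.**  Frame-to-frame displacement is the Euclidean norm of the
difference of consecutive (tx, ty, tz) vectors (mm), and analogously for
rotations kept in degrees; the subject index is the mean over frames, and
exclusion triggers when the *maximum* reaches 1.5 mm or 1.5°.  The limit is
strict (exactly 1.5 fails).  The norm convention — rather than averaging
per-parameter displacements or projecting rotations to arc length — is a
documented choice; only differences matter, so the indices are invariant to
constant offsets.

## Synthetic cohorts and what they show

No subject-level MRI is available for this design, so validation rests on
synthetic cohorts with planted, recoverable structure:

* **Signals.**  Each node is a stationary unit-variance Gaussian AR(1)
  process (default ar = 0.85 at TR = 2 s, concentrating power at low
  frequencies); the node vector is colored by the symmetric PSD square root
  of a target correlation matrix.  Sample inter-node correlations converge
  to the design and lag-1 autocorrelation to the AR coefficient.  The
  default design is block structured (sensorimotor block 0.45, cerebellar
  block 0.45, cortico-cerebellar links 0.25, subcortical pair 0.30,
  bilateral homologues 0.60, baseline 0.10) — values are free parameters of
  the generator chosen to be PSD and broadly brain-like, not estimates.
* **Behavior.**  MPI = intercept (73.3) + Σ c·(feature − cohort mean)
  + slope·(age − 55) within the older half (slope −0.32 ΔE/year, matching
  an age–MPI correlation near −0.5 at the emulated group sizes) + Gaussian
  noise (sd 2.0).  Coupling features are realized edge weights or DCs
  *measured through the default preprocessing chain*, so the planted signal
  lives in exactly the quantity the analysis estimates.  Centering the
  features keeps the intercept interpretable as the cohort baseline.  The
  default plan couples CAnt_L and CPost8_R DC at coefficient 0.8, which
  yields within-group partial correlations around 0.4–0.6 at n = 26 —
  comparable to the effect sizes such studies report — and total MPI sd
  near 3.
* **Motion** is a cumulative Gaussian random walk (step sd 0.02 mm /
  0.015°), far below the exclusion limits by construction.
* **Volumes.**  `render_labelled_volume` paints node signals into labelled
  voxel blocks plus iid noise; mean extraction inverts it exactly at zero
  noise, and with k voxels per region the extraction error shrinks as 1/√k.

Calibration tests (type-I error of hub/edge screening) and recovery tests
use an *identity* inter-node design.  This is deliberate: under a
correlated design the DC sampling fluctuations of different nodes share
variance, so when a coupling is planted on one node, other nodes carry
small *true* induced associations — they are not null, and calling them
false positives would be wrong.  Even under the identity design each
non-planted node shares one incident edge with the planted node's DC, so
its rate is only approximately nominal; the tests bound it at 15% over the
24 nodes rather than at α.

What passing these tests does **not** show: the generator has no
hemodynamic response, physiological (cardiac/respiratory) noise, scanner
drift or spatial structure, and motion is independent of the signals, so
the nuisance regression step removes almost nothing here.  Recovery on
these cohorts validates the estimators and their calibration, not
robustness to real acquisition artifacts.

## Numerical choices and degenerate inputs

* PSD check on covariance designs tolerates eigenvalues ≥ −1e−10 and
  reports the offending eigenvalue; negative eigenvalues within tolerance
  are clipped to 0 before taking the matrix square root.
* Zero-variance node signals, rank-deficient nuisance/covariate designs
  (the offending column is named), missing phenotype cells (subject/line
  named), empty ROI labels, and median-age ties are hard errors, never
  silent repairs.
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; identical specs give bit-identical cohorts,
  and a pipeline run records a config hash so outputs are reproducible.
* Problem sizes used by the test-suite recovery checks — 200 subjects for
  coupling recovery and calibration, 5000 timepoints for covariance
  recovery, 100 random instances for the partial-correlation oracle — were
  chosen so each check has comfortable statistical margin while the whole
  suite stays light.

## Known limitations

* A printed hub list of the kind this analysis produces can contain
  internal inconsistencies (e.g. a node reported as significant alongside
  p = 0.14, a plausible typo); such values are not treated as reproducible
  targets here.
* Whether hub p-values should be one- or two-tailed is a convention; this
  package reports two-tailed p with a positivity filter on r_partial.
* Slice-timing correction, realignment and template normalization are out
  of scope: motion parameters and regional series are consumed as given.
* Scrubbing/censoring of high-motion frames is not implemented; QC is
  index-based exclusion only.
* The analysis is correlational; nothing here supports causal claims about
  connectivity and chewing performance.
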