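# Methods

## Scope and model

`fmribss` implements and compares two estimators of subject-specific
spatial components from multi-subject resting-state fMRI, together with
the group statistics built on their outputs. Both estimators use the
spatial orientation: components are images (k × V maps over in-mask
voxels), voxels are samples, and each subject's temporal dimension is
reduced by PCA before unmixing.

**Group ICA (baseline).** Subject-level PCA to ⌈1.5k⌉ components,
temporal concatenation, group-level PCA to k, Infomax ICA (logistic
nonlinearity, natural gradient), then least-squares back-reconstruction
(dual regression) of subject time courses and maps. This is the
reference both guided methods are meant to improve on: its subject maps
are regression estimates around the common group maps and understate
genuine intersubject variability (ISV).

**GIG-ICA.** For each subject and each group reference map r, the
component y = wᵀz (z the subject's whitened spatial data, ‖w‖ = 1)
maximizes J(w) = λ·(E[G(y)] − E[G(ν)])² + (1−λ)·corr(y, r) with
G = log cosh and ν standard normal. Components are estimated one at a
time in reference order, each initialized at the reference's projection
onto the whitened subspace; optimization is projected gradient ascent on
the unit sphere with backtracking. λ = 0.5 by default. A component whose
final reference correlation falls below 0.2 logs a "reference lost"
warning — under strong ISV the independence term can pull the estimate
to a different source, and downstream pairing thresholds then discard
the component rather than silently mislabel it.

**IVA-GL.** One unmixing matrix per subject, estimated jointly by
relative-gradient descent on Σₖ H(SCVₖ) − Σₛ log|det Wₛ|, where the k-th
source component vector (SCV) stacks component k across subjects. The
Gaussian stage models each SCV as multivariate normal
(H = ½ log det Σₖ + const, scores Σₖ⁻¹Yₖ); the Laplace stage refines
from that solution with the unit-variance multivariate-Laplace score
y/‖y‖ capturing higher-order dependence. Step-halving on any cost
increase, gentle step growth otherwise; tolerance 1e-6, at most 1024
iterations per stage. Because the unmixing is joint, component order is
aligned across subjects by construction.

Everywhere, maps follow one sign convention (largest-|value| voxel
positive) and are z-scored over voxels (mean 0, std 1); both make
outputs deterministic and comparable across methods.

**Infomax details.** Full-batch natural gradient with the logistic
score, initial rate 0.005, annealed down on oscillation of successive
updates and allowed to grow on steady progress; convergence when the
largest weight-update element falls below 1e-6. The iteration cap is
1024: near-Gaussian inputs make the objective nearly flat along
rotations and need more than 512 iterations to satisfy the
weight-change criterion, although the separation itself is reached much
earlier.

## Synthetic cohorts

The generator produces two-group (HC/ASD) cohorts from k latent sources
with controlled, recoverable structure:

* **Sources** are 3-D Gaussian blobs rasterized on the voxel grid
  (unit peak), placed by rejection sampling so pairwise spatial
  correlation stays below 0.3. Blob width defaults to min(grid)/10
  voxels; the ISV study uses 1.75 voxels on a 14³ grid, the scale of
  heavily smoothed fMRI networks. Real networks are not blobs — they
  are distributed, irregular, and anatomically constrained — so passing
  tests show recovery of compact controlled sources, not anatomical
  fidelity.
* **ISV** is per-subject jitter of each blob's centroid
  (N(0, isv_sigma) voxels per axis, clamped to the grid) plus a
  fractional amplitude factor 1 + N(0, amp_sigma).
* **Group variance difference**: ASD subjects' deviations from the base
  map on designated sources are scaled by √var_inflation_asd, which
  multiplies the across-subject voxel variance of those sources by
  exactly var_inflation_asd.
* **Time courses** are draws from a zero-mean multivariate normal with a
  group-specific covariance (the planted FNC), low-pass filtered to
  0–0.1 Hz (4th-order zero-phase Butterworth). The filter output is
  rescaled by the filter's broadband RMS gain so a unit-variance input
  keeps unit variance — the planted covariance, not the filter
  attenuation, sets the source scale, and cross-source correlations are
  untouched. No hemodynamic response, autocorrelation, motion, or
  multi-site structure is modeled: the noise is i.i.d. Gaussian per
  voxel and timepoint, the simplest model under which ICA
  identifiability holds.
* **Defaults**: 15 + 15 subjects, k = 8, 12³ grid, T = 150 at TR = 2 s,
  isv_sigma = 1, amp_sigma = 0.1, var_inflation_asd = 2 on the first two
  sources, noise_sigma = 0.5. Default group covariances plant a 2-block
  (HC) vs 3-block (ASD) correlation structure at r = 0.45 within blocks.
* **Behavioral targets** (`make_behavioral_target`) are linear
  functionals of one component's z-scored subject maps plus Gaussian
  noise at a chosen signal-to-noise amplitude ratio. The default weight
  vector is the first principal axis of the component's across-subject
  map variation, so the score tracks the dominant mode of spatial
  reorganization — the quantity subject-specific decompositions are
  supposed to capture. (A random-weight mode exists as a deliberately
  hard reference: most of a random functional falls outside the maps'
  across-subject variation and is unpredictable by construction.)

## Screening, pairing and network statistics

* **fALFF** is the fraction of the amplitude spectrum (Hann-tapered DFT
  of the demeaned time course) inside 0.01–0.08 Hz relative to
  0–Nyquist; components are kept when fALFF > 0.5 (strict). The taper
  keeps non-bin-aligned oscillations from leaking amplitude out of
  band; for white noise the expected value is the bandwidth fraction
  (0.28 at TR = 2 s).
* **Dynamic range** is the log10 drop from the Welch power-spectrum peak
  to the minimum power above the peak. Welch averaging (segments of
  T/4) is what makes the flat-spectrum baseline flat; a raw periodogram
  would give noise components spuriously large values. The literature
  states no formula for this metric; this is one toolbox convention,
  reported but not used for screening.
* **Greedy pairing**: repeatedly take the globally largest remaining
  |r| cell of the cross-method spatial-correlation matrix, delete its
  row and column, stop at |r| ≤ threshold (0.5). Ties break to the
  lowest (row, column) index. A one-to-many mode keeps each row's best
  column above threshold. Signed r is reported; ordering uses |r|.
* **FNC** is the Pearson correlation of paired components' time courses,
  Fisher r-to-z transformed for statistics; group means average z values
  and back-transform.
* **Modularity** uses signed Louvain with the asymmetric weighting
  Q = Q⁺ − v⁻/(v⁺+v⁻)·Q⁻ (positive weight rewarded, negative penalized
  in proportion to its share), reducing to Newman Q on all-positive
  graphs. Louvain is stochastic: best of 100 repeats (seeded), Q always
  recomputed from the returned partition, singleton communities counted
  in the module count. An exhaustive-partition oracle validates the
  optimum on graphs of ≤ 8 nodes.
* **Inference**: two-sided permutation tests on mean differences (label
  permutation, or sign flipping for paired data), p = (1+#extreme)/(1+n);
  pooled-variance t-tests per FNC edge and per voxel; BH-FDR
  (Benjamini–Hochberg step-up, via statsmodels) for multiplicity. BH
  rather than BY is the field convention for weakly dependent edges and
  voxels.
* **Association**: the boosted statistic PC + sign(PC)·NMI with NMI
  estimated by equal-frequency binning into ⌈√(N/5)⌉ ≤ 16 bins and
  normalized by the mean marginal entropy; Shepherd's pi removes points
  whose bootstrapped (200 resamples) squared Mahalanobis distance from
  the bivariate mean is ≥ 6, then reports Spearman's rho of the
  remainder with its standard p, unadjusted.

## Spatial statistics

Voxelwise two-sample t-tests with BH-FDR over in-mask voxels;
"cluster-level" reporting extracts maximal 6-connected suprathreshold
clusters (minimum extent 10 voxels) at both the uncorrected p < 0.05 and
FDR-corrected thresholds, reporting voxel counts for each. Gaussian
random-field inference is out of scope. Variance maps use the unbiased
(n−1) across-subject variance of z-scored subject maps per group;
the group comparison is a two-sided Wilcoxon signed-rank test across
in-mask voxels pairing the groups' variance values (voxelwise variance
distributions are far from normal; the specific nonparametric test is a
documented choice). Per-network masks threshold the z-scored group
t-map at |z| > 1.96.

The voxel-pairing Wilcoxon treats voxels as exchangeable pairs although
neighboring voxels' variances are driven by the same subjects and are
strongly correlated; its p-values are therefore optimistic in absolute
terms and are best read comparatively (method A vs method B on the same
data), which is how the pipeline uses them.

## Prediction

Per network: feature selection correlates each voxel (restricted to the
network's |z| > 1.96 t-map mask) with the target after residualizing
both on nuisance covariates (sex, handedness; never age when age is the
target), keeping voxels with two-sided p < 0.001. Prediction is LASSO —
objective (1/2N)‖Xω−y‖² + α‖ω‖₁, solved by scikit-learn — inside nested
cross-validation: leave-one-out outer folds; within each training fold,
standardization, a 100-point log-spaced α path from α_max (the smallest
α zeroing all coefficients) down to 10⁻⁴·α_max, and 10-fold inner CV to
pick α. By default selection is re-run inside every outer fold, so the
held-out subject never influences its own feature set; a pooled mode
(selection once on all subjects) is provided because that ordering
appears in practice — on null data it is measurably optimistic, and the
test suite demonstrates the difference. The inner coordinate descent
runs with loosened tolerance (tol 1e-3, ≤ 500 iterations): model
selection across the α path does not need 1e-6 objectives, and the
selected α is unchanged while the path fits run several-fold faster. An
independent cyclic coordinate-descent oracle in the tests confirms the
solver reaches the stated objective on small problems at tight
tolerance. Performance is R² = 1 − SS_res/SS_tot, RMSE, and Spearman's
rho, with a one-sided permutation test (1000 permutations) on the
predicted-vs-observed rank correlation.

## Validation studies and problem sizes

The studies in `fmribss.experiments` (shared by the test suite and
`scripts/acceptance.py`) run at sizes chosen to finish in minutes on one
core while keeping each effect comfortably detectable:

* **ISV comparison**: 25 + 25 subjects, k = 4, 14³ grid, blob σ = 1.75,
  centroid jitter 2 voxels, variance inflation 2 on two sources,
  5 seeds. Measures: total across-subject variance of each method's
  z-scored subject maps (IVA-GL should exceed GIG-ICA, since GIG-ICA
  shrinks toward the references), and the Wilcoxon detection of the
  planted ASD-greater variance aggregated over the designated sources'
  matched components. Aggregation matters: with 25 subjects per group
  the realized variance ratio of a single source fluctuates widely
  around its expectation of 2, and single-component tests are
  underpowered even on the true maps.
* **Modularity difference**: per-subject module counts from planted
  2-block vs 3-block FNC at 15 + 15, paired permutation test, 10
  replicate cohorts for power.
* **Prediction recovery**: 80 + 80 subjects (sparse-regression pipelines
  need cohorts at the scale of the ~180-subject studies this emulates),
  k = 4, scan noise 0.1 (recovery-grade), target on one component at
  signal-to-noise 2, features from the GIG-ICA maps of the matched
  component inside its t-map mask. Null control: pure-noise feature
  sets of a small cohort must stay insignificant in ≥ 90% of replicates.
* **Calibration**: type-I error of the permutation test over 500 null
  replicates; BH-FDR equivalence with a literal step-up implementation
  over 1000 random p-vectors; Louvain vs exhaustive partitions on all
  fixture graphs ≤ 8 nodes.

## Known limitations

* The generator's spatial and temporal models are deliberately minimal
  (blobs, filtered Gaussian time courses, white noise); conclusions
  about real fMRI transfer only to the extent that these capture the
  relevant structure (compact coherent sources, band-limited dynamics,
  map-level ISV).
* GIG-ICA can lose weakly correlated references under strong ISV; this
  is reported by warning and handled by pairing thresholds, not
  prevented.
* Model order is assumed known (it is, for synthetic data); no order
  estimation is provided.
* fALFF screening on estimated time courses inherits their regression
  noise; at high scan-noise settings real components can fall below the
  0.5 threshold. The generator's default noise level keeps them above
  it.
* The variance-difference test's voxel-exchangeability caveat above.
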