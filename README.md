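# fmribss

Multi-subject blind source separation for resting-state fMRI: a tested,
reusable pipeline comparing **GIG-ICA** (group-information-guided
independent component analysis) and **IVA-GL** (independent vector
analysis with a Gaussian-then-Laplace source prior) on the network
properties they extract — functional network connectivity (FNC) and its
modularity, spatial mean and variance statistics, and sparse-regression
prediction of behavioral scores — together with a synthetic-cohort
generator that provides recoverable ground truth for every stage.

## Who this is for

Researchers analyzing multi-subject resting-state fMRI who want
subject-specific spatial maps and time courses from the two families of
estimators that handle intersubject variability (ISV) differently:

* **GIG-ICA** estimates each subject's component `y = wᵀz` (z = the
  subject's spatially whitened data) by maximizing
  `J(w) = λ·Ĵ(y) + (1−λ)·corr(y, rₖ)`, a weighted sum of the negentropy
  surrogate `Ĵ(y) = (E[G(y)] − E[G(ν)])²` with `G = log cosh` and the
  correlation with the group-level reference map `rₖ` — independence
  guided by group information.
* **IVA-GL** estimates one unmixing matrix per subject jointly by
  minimizing `Σₖ H(SCVₖ) − Σₛ log|det Wₛ|`, where the k-th source
  component vector (SCV) collects component k across all subjects — a
  multivariate Gaussian stage captures second-order dependence across
  subjects, then a multivariate Laplace stage refines with higher-order
  structure. No back-reconstruction step is needed and component order is
  aligned across subjects by construction.

Downstream, the pipeline screens components by fALFF (fraction of
spectral amplitude in 0.01–0.08 Hz), pairs the two methods' components by
the greedy rule on spatial correlations (|r| > 0.5), builds per-subject
Fisher-z FNC matrices, runs signed Louvain modularity
(`Q = Q⁺ − v⁻/(v⁺+v⁻)·Q⁻`), permutation tests and BH-FDR edge statistics,
voxelwise mean/variance group comparisons, Shepherd's pi robust
correlation, and connectome-style prediction (CPM voxel selection at
p < 0.001, then LASSO `min_ω (1/2N)‖Xω−y‖² + α‖ω‖₁` in a nested
leave-one-out / 10-fold cross-validation).

## Worked example

```python
import numpy as np
from fmribss import (SimConfig, assemble_dataset, group_ica, gig_ica,
                     iva_gl, zscore_maps, greedy_pair, compute_fnc,
                     fisher_z_fnc, louvain_modularity, chi_square_2x2)

# demographic table check: males/females 65/10 (HC) vs 76/26 (ASD)
chi2, p = chi_square_2x2(65, 10, 76, 26)
print(f"gender chi-square = {chi2:.3f}, p = {p:.3f}")

# synthetic two-group cohort with known sources
cfg = SimConfig(n_hc=8, n_asd=8, k_sources=4, grid_shape=(10, 10, 10),
                n_timepoints=120, seed=0)
dataset, truth = assemble_dataset(cfg)

baseline = group_ica(dataset, k=4, seed=0)      # references
gig = gig_ica(dataset, baseline.group_maps, seed=0)
iva = iva_gl(dataset, k=4, seed=0)

# cross-method pairing on z-scored mean maps
pairing = greedy_pair(np.mean([zscore_maps(m) for m in iva.spatial_maps], 0),
                      np.mean([zscore_maps(m) for m in gig.spatial_maps], 0))
print("paired components:", [(i, j, round(r, 3)) for i, j, r in pairing.pairs])

# per-subject FNC modularity for one method
z = fisher_z_fnc(compute_fnc(gig.timecourses[0])).values
mod = louvain_modularity(z, n_repeats=100, seed=0)
print(f"subject 0: Q = {mod.q:.3f}, modules = {mod.n_modules}")
```

Output:

```
gender chi-square = 3.942, p = 0.047
paired components: [(0, 2, 0.94), (1, 0, 0.887), (2, 1, 0.95), (3, 3, 0.885)]
subject 0: Q = 0.134, modules = 2
```

The chi-square reproduces the demographic-table p-value; the four
synthetic sources pair one-to-one across the two methods with spatial
|r| ≈ 0.9; and the subject's FNC splits into the two planted
connectivity blocks.

A shell interface wraps the same pipeline:

```bash
fmribss simulate --seed 0 --out data/ --subjects 15 --k 8
fmribss run-all --input data/ --out results/ --seed 0
```

Stages are idempotent — deleting one stage's outputs and re-running
recomputes only that stage — and every run writes a JSON manifest with
per-stage output hashes.

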