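# smncent

Voxel-wise functional network centrality within a masked brain network,
for resting-state fMRI.  `smncent` is aimed at neuroimaging researchers
who want to quantify how central each voxel of a network (for example a
sensorimotor-network template) is within the network's voxel-wise
functional connectome, compare centrality between groups with proper
cluster-level multiple-comparison control, and relate the resulting
clusters to clinical measures such as EDSS disability scores, brain
parenchymal fraction (BPF) and white-matter lesion load (TWMLL).

## The statistics at the core

Given the row-standardised in-mask time-series matrix **Z** (N voxels x
T volumes), with Pearson correlations r_ij = z_i . z_j / (T-1):

* **Degree centrality** — direct connection strength of voxel i:

      DC(i) = Σ_{j≠i} r_ij · [ r_ij > r0 ]        (weighted, r0 = 0.25)

  computed for r0 in {0.1, …, 0.4} in one blockwise pass; the N×N
  correlation matrix is never stored.

* **Eigenvector centrality** — the unique nonnegative principal
  eigenvector u of A = (C + 1)/2:

      A u = λ₁ u,   u ≥ 0,   ‖u‖ = 1

  obtained matrix-free by power iteration via
  A·v = (Z(Zᵀv)/(T−1) + **1**·Σv)/2.

Per-subject maps are global-mean normalised (k/k0, u/u0),
rank-Gaussianised (EC) and converted for group analysis; group
differences are assessed with voxel-wise GLM t/F statistics (age and
gender covariates, paired designs supported) and corrected by
Monte-Carlo simulation of the null maximum cluster extent (per-voxel
P = 0.01, FWHM 6 mm, rmm 5 mm neighbourhood, 1000 iterations, corrected
alpha 0.05).  A synthetic-study generator with closed-form ground truth
(community latent signals + AR(1) noise, planted effects, coupled
clinical covariates) backs every stage with recoverable truth.

## Worked example

```python
import smncent as sc

# a 1000-voxel connected toy network on a 12^3 grid of 3 mm voxels
mask = sc.make_toy_mask((12, 12, 12), 1000, seed=11)
hubs = sc.default_hub_spec(mask, n_communities=6, weight=0.8, seed=12)
img = sc.simulate_subject_timeseries(mask, hubs, T=120, seed=13)

img = sc.smooth_gaussian(img, fwhm_mm=6.0)
vm = sc.extract_matrix(img, mask)
vm = sc.bandpass(vm, tr_seconds=2.0)          # 0.01-0.08 Hz
zvm, flagged = sc.standardize_rows(vm)

dc = sc.degree_centrality(zvm, r0=0.25)
ec = sc.fast_eigenvector_centrality(zvm)
print(f"mean DC {dc.values.mean():.1f}, max DC {dc.values.max():.1f}")
print(f"EC lambda1 {ec.lambda1:.1f} after {ec.n_iterations} iterations")
```

prints

```
mean DC 225.1, max DC 482.4
EC lambda1 633.3 after 14 iterations
```

i.e. on this smoothed, community-structured fixture an average voxel
carries a supra-threshold correlation sum of ~225 (of 999 possible
neighbours), the most central voxel more than twice that, and the
shifted correlation matrix has a dominant eigenvalue of ~633 (≈ N/2
from the uniform shift plus the community structure), reached in 14
matrix-free iterations.

An end-to-end synthetic study — preprocessing, DC at all thresholds +
EC, two-sample/paired/ANCOVA statistics, cluster correction, clinical
regression, and a checksum manifest — runs with:

```bash
smncent run --seed 42 --out runs/demo          # or: sc.run_study(sc.RunConfig(seed=42), "runs/demo")
```

Re-running from `runs/demo/manifest.json` reproduces every output
bit-identically.

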