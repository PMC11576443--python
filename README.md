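# conntarget

Connectome-guided TMS stimulation-site planning for hippocampal targets on
the left lateral parietal cortex (LLPC), with a test–retest
reproducibility analysis — implemented as a desk-scale, fully testable
pipeline driven by synthetic data with planted ground truth.

## The problem

Repetitive transcranial magnetic stimulation (rTMS) can only stimulate
superficial cortex directly (depth < ~30 mm), but its effects propagate
along networks, so deep structures such as the hippocampus are reached by
stimulating a superficial site that is *connected* to them.  Two
personalization strategies compete:

* **FC-guided**: from resting-state fMRI, correlate the mean signal of a
  hippocampal seed with every brain voxel (seed-to-voxel Pearson *r*) and
  stimulate where the parietal correlation is strongest;
* **SC-guided**: from diffusion tractography, count streamlines launched
  in the seed that reach each cortical voxel, normalize by the number
  launched (a tract-probability map), and stimulate where the probability
  is highest.

Either map is restricted to a binary LLPC mask, cluster-thresholded at
the 10th percentile (top decile of positive in-mask values), labeled into
connected components, and the value-weighted center of gravity (COG) of
the best-ranked cluster within TMS reach (< 30 mm from the scalp surface)
becomes the stimulation coordinate.  Reproducibility is quantified by the
intra-individual Euclidean distance between the targets a strategy
produces at two scan timepoints (after an affine transform to MNI space),
compared across strategies with Welch's unequal-variance *t*-test, plus a
subregion-stability analysis against a parietal parcellation
(PGs, PGi, PFm, PF, IP0, IP1).

## What is in the package

| module | contents |
| --- | --- |
| `conntarget.core_io` | `Volume3D` / `TimeSeries4D` / `LabelVolume` / `SurfaceMesh` / `AffineTransform`, NIfTI/TSV/OFF/affine-text I/O, report writer |
| `conntarget.synthetic_data` | BOLD-like 4-D series with planted seed-correlated clusters, tract-probability volumes with planted hotspots, orientation fields, toy parietal atlases, ellipsoid scalp meshes, two-timepoint cohort simulations |
| `conntarget.fc_mapping` | confound regression, 0.01–0.1 Hz band-pass, 5-mm FWHM smoothing, seed-to-voxel correlation |
| `conntarget.sc_mapping` | toy probabilistic tracker (0.5-mm steps, 0.2 curvature-cosine threshold, loop check, exact streamline accounting) and count normalization / ingest |
| `conntarget.target_selection` | masking, decile thresholding, 6/18/26-connectivity clustering, COG ranking, scalp-depth constraint |
| `conntarget.reproducibility_stats` | MNI transform, distances, Welch's *t* and Shapiro–Wilk (implemented from scratch), subregion assignment, stability matrices |
| `conntarget.cli` | `conntarget simulate / fc-target / sc-target / compare` |

## Worked example

```python
import numpy as np
import conntarget as ct

# --- plan an FC-guided target on synthetic data with known truth -------
masks = ct.default_masks((28, 32, 28))                 # 2 mm grid
truth = ct.plant_cluster(masks["parietal"], radius_mm=5.0,
                         planted_r=0.85, rng_seed=7)
ts, confounds, _ = ct.make_synthetic_fmri(
    masks["seed"], masks["parietal"], truth, noise_sd=0.5, rng_seed=7)
cmap = ct.fc_connectivity_map(ts, confounds, masks["seed"], masks["brain"])
mesh = ct.make_scalp_mesh((55.0, 55.0, 55.0))
target = ct.select_target(cmap, masks["parietal"], mesh)

# --- compare strategy reproducibility on a simulated 30-subject cohort -
k_sc, th_sc = ct.gamma_jitter_from_moments(12.2, 5.9)    # SC jitter scale
k_fc, th_fc = ct.gamma_jitter_from_moments(24.75, 12.57) # FC jitter scale
pairs = {}
for name, (k, th), seed in (("SC", (k_sc, th_sc), 11), ("FC", (k_fc, th_fc), 12)):
    cfg = ct.CohortSimConfig(n_subjects=30,
        jitter_model={"gamma_sigma": {"shape": k, "scale": th}}, rng_seed=seed)
    pairs[name] = ct.make_cohort_displacements(cfg)
report = ct.compare_strategies(ct.CohortTargets.from_pairs(
    pairs["SC"][0], pairs["SC"][1], pairs["FC"][0], pairs["FC"][1]))
```

This prints (exact output of the snippet above):

```
planted target (mm):   [17. 17. 11.]
FC-guided target (mm): [17. 17. 11.]  depth 28.8 mm  rank 1  reachable True
recovery error: 0.07 mm

SC: intra-individual distance 11.50 +/-  6.15 mm   Shapiro-Wilk W = 0.935 (p = 0.068)
FC: intra-individual distance 22.45 +/- 10.95 mm   Shapiro-Wilk W = 0.943 (p = 0.110)
Welch t = -4.778, df = 45.6, p = 1.87e-05
```

The planted parietal cluster is recovered to a fraction of a voxel, and
the simulated cohort — whose per-strategy jitter scales are
moment-matched to intra-individual distances of 12.2 ± 5.9 mm (SC) vs
24.75 ± 12.57 mm (FC) — shows the SC-guided strategy's significantly
tighter test–retest reproducibility (negative Welch *t*, *p* < 0.0001).

The same pipeline runs from the shell:

```bash
conntarget simulate --out fixture/ --seed 1
conntarget fc-target --fmri fixture/fmri.nii.gz --confounds fixture/confounds.tsv \
    --seed-mask fixture/seed_mask.nii.gz --brain-mask fixture/brain_mask.nii.gz \
    --parietal-mask fixture/parietal_mask.nii.gz --scalp-mesh fixture/scalp.off \
    --out fc_target.json
```

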