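# Methods

This note documents the models and procedures implemented in
`conntarget`, the choices made where a published description is ambiguous
or silent, and what the synthetic test conditions do and do not
establish.

## Coordinate conventions

Voxel indices are 0-based; a voxel's world position is its center; world
coordinates are continuous millimetres in RAS+; the world position of
voxel `v` is `affine @ [v, 1]`.  All geometry (COGs, depths, distances)
is computed in world mm; grid operations (smoothing, clustering) take
per-axis voxel spacing from the affine's column norms, so anisotropic
grids are handled.  Only affine native→MNI transforms are supported;
nonlinear warps are out of scope.

## FC mapping

Pipeline order: **confound regression → band-pass → seed extraction →
smoothing → correlation**.

* *Confound regression.* Every voxel's series is replaced by its OLS
  residual against `[1, confounds]`.  Residuals are orthogonal to every
  confound column by construction; a rank-deficient design is an error
  that names the redundant columns.  The pipeline accepts any confound
  table; which nuisance signals are included materially affects
  FC-target stability, and no specific set is prescribed here.
* *Band-pass 0.01–0.1 Hz.* Realized by default as a zero-phase hard
  frequency-domain mask applied to linearly detrended series.  Only the
  band edges are part of the method definition; the hard mask is chosen
  because its passband (gain 1) and stopband (gain 0) are exactly
  testable.  A zero-phase 5th-order Butterworth is available via
  `method="butter"` for users who prefer a conventional IIR realization.
* *Smoothing, FWHM 5 mm.* Gaussian with σ = FWHM/(2√(2 ln 2)) mm,
  converted to voxel units per axis.  Smoothing is applied to the
  filtered series entering the correlation; the seed mean is extracted
  from the regressed, filtered but *unsmoothed* data.  Both choices are
  recorded in the map metadata.
* *Correlation.* Pearson r of the seed mean with every voxel.
  Zero-variance voxels get r = 0 (count logged and stored in metadata)
  rather than NaN, keeping percentile thresholding total.  Only positive
  correlations can become targets (negative values never survive the
  positive-decile threshold).

## SC mapping

The SC route consumes a termination-count volume and a launched-streamline
total, from either source:

* *Ingest*: a precomputed tractography count volume plus its waytotal.
* *Toy tracker*: streamlines launched uniformly inside each seed voxel
  (default 50,000 per seed voxel; tests use hundreds), advanced 0.5 mm
  per step along the local orientation, terminated on entering the
  termination mask, leaving the volume, exceeding `max_steps`, turning
  with cosine < 0.2 between successive steps, or re-entering a voxel
  already visited (the loop check).  Accounting is exact — the six
  fates partition the launched total — and asserted on every run.

Orientation vectors are treated as sign-free axes by default (the
standard reading of diffusion orientations): each step takes the sign
maximizing the cosine with the previous step, the first step's sign
being random.  Synthetic fields that deliberately reverse direction are
only informative when the stored sign is honored, so the axial handling
is a config switch (`orientation_is_axial`).

The probability map is `counts / launched_total`.  The normalization
denominator is read as the number of streamlines *launched* from the
seed; dividing by the number that survived to the target is available
via `denominator="surviving"` for the alternative reading, and the choice
is stored in the map metadata.

## Target selection

* *Decile threshold.* "Cluster thresholding at the 10th percentile" is
  implemented as retaining the top 10 % of positive in-mask values —
  `ceil(0.1 P)` voxels plus ties at the cut — consistent with selecting
  the most robust positive connectivity.  The literal alternative
  (discard the bottom 10 %) is config-selectable.
* *Clustering.* Connected components at 26-connectivity by default
  (6/18 selectable); cluster mass and COG use the original map values.
* *Ranking.* Clusters are ranked by value-weighted mass (ties: larger
  peak value, then lower id).  A center of gravity is a location, not an
  ordinal, so "highest COG" is operationalized as largest mass, with the
  returned coordinate at the winning cluster's value-weighted COG;
  peak-value ranking is available via `rank_by="peak"`.  Whether a study
  reports COGs or peak voxels is ambiguous; this package reports COGs
  and says so in the output metadata.
* *Depth constraint.* Depth is the minimum distance from the COG to the
  scalp-surface vertices (matching a discretely sampled outer-skin
  surface); exact point-to-triangle distance is available via
  `depth_method="surface"`.  Walking down the ranking, the first cluster
  with depth < 30 mm wins.  No published fallback exists for the case
  where no cluster is reachable; here the minimum-depth cluster is
  returned flagged `reachable=False` with a warning.

## Reproducibility statistics

Intra-individual distance is the Euclidean distance between a subject's
T1 and T2 targets *after* the affine MNI transform.  Shapiro–Wilk (per
strategy) and Welch's t (SC vs FC, two-sided, Welch–Satterthwaite df) are
implemented directly; p-values come from the Student-t and standard
normal reference distributions, and Royston's 1995 approximation supplies
the Shapiro–Wilk coefficients and null (n between 3 and 5000).  Both are
validated against independent scipy oracles at 1e-9 (statistics) /
1e-6 (p-values).  No multiple-testing correction is applied — there is a
single primary comparison.

The subregion analysis assigns each target the atlas label of its
containing voxel, snapping background hits to the nearest labeled voxel
within 6 mm ("unassigned" beyond that).  The stability matrix counts
subjects by (T1 region, T2 region); its diagonal fraction is reported
both as a fraction and as a rounded integer percentage with subjects as
the denominator.  The inter-strategy separation is the SC–FC distance
pooled over subjects and both timepoints.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *structure* the pipeline consumes, with
planted, recoverable truth:

* BOLD-like series: a band-limited (0.01–0.1 Hz) unit-variance latent
  signal shared by all seed voxels; planted cluster voxels carry
  `r·s + √(1−r²)·e` with independent band-limited unit-variance noise,
  so their population correlation with the seed equals the planted r
  exactly; all voxels receive random loadings on six confound columns
  (linear/quadratic drifts plus in- and out-of-band sinusoids) and white
  noise.  Defaults follow the emulated acquisition: TR 3 s, 160
  timepoints (8 min), 2 mm isotropic grids.
* Tract-probability stand-ins: a compact Gaussian bump (support 3σ,
  σ = 4 mm) peaking at the true target over uniform background noise.
* Toy atlases: seeded Voronoi partitions of the parietal mask; with six
  regions the standard LLPC subregion names are used.
* Scalp surfaces: subdivided icospheres scaled to ellipsoids
  (default semi-axes 85 × 105 × 80 mm).
* Cohorts: T2 = T1 + d with d ~ N(0, σ²I₃), so ‖d‖ ~ σ·chi(3) and
  E‖d‖ = 2σ√(2/π).  A single σ per strategy fixes SD/mean at
  √(3π/8 − 1) ≈ 0.422, *below* the reported ratios (0.48 SC, 0.51 FC),
  so cohort heterogeneity is modeled by per-subject σᵢ ~ Gamma(k, θ)
  with k, θ solved in closed form so the cohort distance mean and SD hit
  requested targets simultaneously.  This heterogeneity model is a
  modeling choice, not an observed quantity — per-subject raw distances
  are not published — and fixture metadata flags it as such.

Not emulated: hemodynamics, scanner noise spectra, motion and
susceptibility artifacts, gyral anatomy, crossing fibers, nonlinear
registration.  Passing tests therefore establish that the *machinery* is
correct (each stage matches its oracle, planted truth is recovered,
group statistics behave as derived), not that either strategy attains
any particular reproducibility on real MRI data.

## Numerical choices and degenerate inputs

* Every generator and the tracker are pure functions of their
  `rng_seed`; acceptance simulations derive per-replicate seeds from a
  single seeded generator (kept below 2³¹).
* Decile ties at the cut are all retained; cluster id order breaks exact
  rank ties deterministically.
* Constant voxels: r = 0 (flagged); constant seed series: error.
* Degenerate cohorts (zero variance in both strategies' distances) yield
  a report whose Welch field is a sentinel string rather than an error.
* Problem sizes in the test suite are desk-scale by design: 24–28-voxel
  grids, 120–160 timepoints, hundreds of streamlines per seed voxel,
  100-seed recovery ensembles, 1,000-replicate Welch calibrations at
  n = 10,000 / 30 subjects.

## Known limitations

* The tracker samples the orientation field piecewise-constant at voxel
  centers and models a single fiber population per voxel.
* Vertex-sampled scalp depth overestimates the true surface distance by
  up to about half a mesh edge; use `depth_method="surface"` where that
  matters.
* Subregion assignment is nearest-voxel with a 6-mm snap; no partial
  volume handling.
* The Gamma heterogeneity model matches two moments of the distance
  distribution; higher moments are unconstrained.
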