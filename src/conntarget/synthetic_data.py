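"""Synthetic inputs for every stage of the targeting pipeline.

Raw multimodal MRI from the underlying test-retest study is not publicly
deposited, so this module generates stand-ins with *planted, known truth*
for every input the pipeline consumes:

* BOLD-like 4-D series in which a chosen parietal cluster carries a known
  correlation with the seed region's latent signal (plus confounds and
  noise) — the FC strategy must recover the cluster;
* tract-probability volumes with a planted hotspot — the SC ingest path;
* orientation fields (straight, curved, doubling-back) for the toy
  tracker's geometry and termination rules;
* toy multi-region parietal atlases (seeded Voronoi partition);
* ellipsoid scalp meshes (subdivided icospheres);
* two-timepoint cohort displacement simulations whose group moments can
  be matched to reported values, for the reproducibility statistics.

Every generator is a pure function of its ``rng_seed``.  Defaults follow
the study conditions: TR 3 s, 8-minute runs (160 timepoints), 2 mm
isotropic grids, 30-subject cohorts, 50,000 streamlines per seed voxel
(tests scale these down explicitly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .core_io import LabelVolume, SurfaceMesh, Volume3D, TimeSeries4D
import pandas as pd

from .sc_mapping import OrientationField

__all__ = [
    "PlantedTruth",
    "CohortSimConfig",
    "default_grid",
    "default_masks",
    "plant_cluster",
    "make_synthetic_fmri",
    "make_orientation_field",
    "make_synthetic_probability_map",
    "make_toy_atlas",
    "make_scalp_mesh",
    "make_cohort_displacements",
    "gamma_jitter_from_moments",
    "CHI3_MEAN_FACTOR",
    "PARIETAL_LABELS",
]

#: E[||d||] / sigma for d ~ N(0, sigma^2 I_3): mean of a chi(3) variable.
CHI3_MEAN_FACTOR = 2.0 * np.sqrt(2.0 / np.pi)

#: The six left-lateral-parietal subregion names used when a toy atlas is
#: built with exactly six regions.
PARIETAL_LABELS = ("PGs", "PGi", "PFm", "PF", "IP0", "IP1")


@dataclass
class PlantedTruth:
    """Ground truth planted into a synthetic volume, for recovery tests."""

    true_target_world: np.ndarray  # mm
    cluster_voxels: np.ndarray  # (k, 3) int voxel indices
    planted_r: float | None = None  # target Pearson correlation, (0, 1]
    planted_probability_peak: float | None = None

    def __post_init__(self) -> None:
        self.true_target_world = np.asarray(self.true_target_world, dtype=float)
        self.cluster_voxels = np.asarray(self.cluster_voxels, dtype=int)
        if self.planted_r is not None and not 0 < self.planted_r <= 1:
            raise ValueError("planted_r must lie in (0, 1]")


@dataclass
class CohortSimConfig:
    """Two-timepoint cohort displacement simulation.

    ``jitter_model`` is either ``{"fixed_sigma": s}`` (every subject's T2
    displacement has iid Normal(0, s^2) components) or
    ``{"gamma_sigma": {"shape": k, "scale": th}}`` (per-subject sigma_i
    drawn once from a Gamma, giving heterogeneous reproducibility across
    subjects).
    """

    n_subjects: int = 30
    jitter_model: dict = field(default_factory=lambda: {"fixed_sigma": 5.0})
    rng_seed: int = 0
    center_world: tuple[float, float, float] = (-43.0, -71.0, 36.0)
    between_subject_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if "fixed_sigma" in self.jitter_model:
            if self.jitter_model["fixed_sigma"] < 0:
                raise ValueError("sigma must be non-negative")
        elif "gamma_sigma" in self.jitter_model:
            g = self.jitter_model["gamma_sigma"]
            if g["shape"] <= 0 or g["scale"] <= 0:
                raise ValueError("gamma shape and scale must be positive")
        else:
            raise ValueError("jitter_model needs 'fixed_sigma' or 'gamma_sigma'")


def default_grid(
    shape: tuple[int, int, int] = (40, 48, 40), voxel_mm: float = 2.0
) -> tuple[tuple[int, int, int], np.ndarray]:
    """Grid used throughout the synthetic fixtures: 2 mm isotropic,
    world origin at the grid center."""
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = voxel_mm
    affine[:3, 3] = -voxel_mm * (np.asarray(shape) - 1) / 2.0
    return tuple(shape), affine


def _box_mask(shape, affine, lo, hi) -> Volume3D:
    data = np.zeros(shape, dtype=np.uint8)
    data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = 1
    return Volume3D(data, affine)


def default_masks(
    shape: tuple[int, int, int] = (40, 48, 40), voxel_mm: float = 2.0
) -> dict[str, Volume3D]:
    """Seed ("hippocampal body"), parietal and brain masks on the default
    grid: the seed is a small deep block, the parietal mask a superficial
    box in the upper posterior quadrant, the brain mask an ellipsoid that
    contains both."""
    shape, affine = default_grid(shape, voxel_mm)
    nx, ny, nz = shape
    seed = _box_mask(shape, affine,
                     (nx // 2 - 2, ny // 2 - 2, nz // 2 - 4),
                     (nx // 2 + 1, ny // 2 + 1, nz // 2 - 1))
    parietal = _box_mask(shape, affine,
                         (int(nx * 0.55), int(ny * 0.55), int(nz * 0.55)),
                         (int(nx * 0.92), int(ny * 0.92), int(nz * 0.92)))
    ii, jj, kk = np.indices(shape)
    c = (np.asarray(shape) - 1) / 2.0
    brain = ((ii - c[0]) ** 2 / (0.48 * nx) ** 2
             + (jj - c[1]) ** 2 / (0.48 * ny) ** 2
             + (kk - c[2]) ** 2 / (0.48 * nz) ** 2) <= 1.0
    brain |= parietal.data > 0
    brain |= seed.data > 0
    return {
        "seed": seed,
        "parietal": parietal,
        "brain": Volume3D(brain.astype(np.uint8), affine),
    }


def plant_cluster(
    parietal_mask: Volume3D,
    center_world: np.ndarray | None = None,
    radius_mm: float = 5.0,
    planted_r: float | None = 0.85,
    planted_probability_peak: float | None = None,
    rng_seed: int = 0,
) -> PlantedTruth:
    """Choose a ball of in-mask voxels around a center as the planted
    cluster.  With ``center_world=None`` a center well inside the mask is
    drawn reproducibly from ``rng_seed``."""
    mask = np.asarray(parietal_mask.data) > 0
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise ValueError("parietal mask is empty")
    world = parietal_mask.voxel_to_world(idx)
    if center_world is None:
        rng = np.random.default_rng(rng_seed)
        # restrict to voxels whose radius_mm-ball stays inside the mask
        tree = cKDTree(world)
        counts = np.array([len(tree.query_ball_point(w, radius_mm)) for w in world])
        full = counts >= counts.max() * 0.999
        center_world = world[rng.choice(np.where(full)[0])]
    center_world = np.asarray(center_world, dtype=float)
    dist = np.linalg.norm(world - center_world, axis=1)
    cluster = idx[dist <= radius_mm]
    if len(cluster) == 0:
        raise ValueError("planted cluster has no voxels inside the mask")
    return PlantedTruth(center_world, cluster, planted_r, planted_probability_peak)


def _bandlimited_signal(
    rng: np.random.Generator, n: int, tr: float, low: float = 0.01, high: float = 0.1,
    size: int | None = None,
) -> np.ndarray:
    """Unit-variance zero-mean signal(s) with support in [low, high] Hz."""
    freqs = np.fft.rfftfreq(n, d=tr)
    band = (freqs >= low) & (freqs <= high)
    shape = (n // 2 + 1,) if size is None else (size, n // 2 + 1)
    spec = np.zeros(shape, dtype=complex)
    spec[..., band] = rng.normal(size=(*shape[:-1], band.sum())) + 1j * rng.normal(
        size=(*shape[:-1], band.sum())
    )
    x = np.fft.irfft(spec, n=n, axis=-1)
    x -= x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd == 0, 1.0, sd)


def make_synthetic_fmri(
    seed_mask: Volume3D,
    parietal_mask: Volume3D,
    truth: PlantedTruth,
    tr: float = 3.0,
    n_timepoints: int = 160,
    noise_sd: float = 0.5,
    confound_cols: int = 6,
    confound_amp: float = 0.5,
    rng_seed: int = 0,
) -> tuple[TimeSeries4D, pd.DataFrame, PlantedTruth]:
    """BOLD-like 4-D series with a seed-correlated planted cluster.

    All seed voxels share a common band-limited (0.01-0.1 Hz) latent
    signal s(t).  Each planted cluster voxel carries
    ``planted_r * s + sqrt(1 - planted_r^2) * e`` with e independent,
    band-limited and unit-variance, so the population correlation with
    s equals ``planted_r`` exactly.  Every voxel additionally receives a
    random linear combination of the confound columns (scaled by
    ``confound_amp``) plus white noise of sd ``noise_sd``.  The confound
    table is returned for nuisance regression.
    """
    if truth.planted_r is None:
        raise ValueError("truth must carry planted_r for an fMRI simulation")
    smask = np.asarray(seed_mask.data) > 0
    pmask = np.asarray(parietal_mask.data) > 0
    if (smask & pmask).any():
        raise ValueError("seed and parietal masks overlap")
    if tuple(seed_mask.shape) != tuple(parietal_mask.shape):
        raise ValueError("masks are on different grids")
    rng = np.random.default_rng(rng_seed)
    shape = seed_mask.shape
    nvox = int(np.prod(shape))
    r = truth.planted_r

    s = _bandlimited_signal(rng, n_timepoints, tr)

    data = rng.normal(0.0, 1.0, size=(nvox, n_timepoints)) * noise_sd
    flat = data.reshape(nvox, n_timepoints)

    seed_lin = np.flatnonzero(smask.ravel())
    flat[seed_lin] += s

    clus_lin = np.ravel_multi_index(truth.cluster_voxels.T, shape)
    e = _bandlimited_signal(rng, n_timepoints, tr, size=len(clus_lin))
    flat[clus_lin] += r * s + np.sqrt(1.0 - r * r) * e

    if confound_cols > 0:
        tgrid = np.arange(n_timepoints) * tr
        cols = []
        names = []
        for j in range(confound_cols):
            if j == 0:
                c = tgrid / tgrid[-1] - 0.5  # linear drift
                names.append("drift_linear")
            elif j == 1:
                c = (tgrid / tgrid[-1] - 0.5) ** 2
                names.append("drift_quadratic")
            else:
                f = 0.005 * j if j % 2 == 0 else 0.12 + 0.02 * j
                c = np.sin(2 * np.pi * f * tgrid + rng.uniform(0, 2 * np.pi))
                names.append(f"physio_{f:.3f}Hz")
            c = (c - c.mean()) / (c.std() if c.std() > 0 else 1.0)
            cols.append(c)
        C = np.column_stack(cols)
        loadings = rng.normal(0.0, confound_amp, size=(nvox, confound_cols))
        flat += loadings @ C.T
        confounds = pd.DataFrame(C, columns=names)
    else:
        confounds = pd.DataFrame(index=range(n_timepoints))

    ts = TimeSeries4D(flat.reshape(*shape, n_timepoints), seed_mask.affine, tr)
    return ts, confounds, truth


def make_orientation_field(
    shape: tuple[int, int, int],
    affine: np.ndarray,
    pattern: str,
    curve_radius_mm: float = 20.0,
) -> OrientationField:
    """Unit-vector field for the toy tracker.

    ``uniform_x``: every vector is (1, 0, 0).  ``curved``: the direction
    rotates in the x-y plane as a function of world x with turning radius
    ``curve_radius_mm`` — two samples separated by dx subtend an angle
    dx / radius, so a streamline advancing along the field turns with
    per-step cosine ~ 1 - (step/radius)^2 / 2.  ``doubling_back``:
    (1, 0, 0) in the low-x half, (-1, 0, 0) in the high-x half, to
    exercise the curvature threshold and loop check.
    """
    shape = tuple(shape)
    data = np.zeros((*shape, 3))
    ii = np.indices(shape).reshape(3, -1).T.astype(float)
    world_x = (ii @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3])[:, 0]
    world_x = world_x.reshape(shape)
    if pattern == "uniform_x":
        data[..., 0] = 1.0
    elif pattern == "curved":
        if curve_radius_mm <= 0:
            raise ValueError("curve_radius_mm must be positive")
        phi = (world_x - world_x.min()) / curve_radius_mm
        data[..., 0] = np.cos(phi)
        data[..., 1] = np.sin(phi)
    elif pattern == "doubling_back":
        mid = 0.5 * (world_x.min() + world_x.max())
        data[..., 0] = np.where(world_x < mid, 1.0, -1.0)
    else:
        raise ValueError(f"unknown orientation pattern {pattern!r}")
    return OrientationField(data, affine)


def make_synthetic_probability_map(
    parietal_mask: Volume3D,
    truth: PlantedTruth,
    background_level: float = 1e-5,
    hotspot_sigma_mm: float = 4.0,
    rng_seed: int = 0,
) -> Volume3D:
    """Non-negative tract-probability stand-in with a compact planted
    hotspot peaking at the true target.

    The hotspot is a truncated Gaussian bump (support within 3 sigma) of
    height ``truth.planted_probability_peak``; the background is uniform
    noise on [0, background_level] inside the mask.
    """
    if background_level < 0:
        raise ValueError("background_level must be non-negative")
    peak = truth.planted_probability_peak
    if peak is None:
        raise ValueError("truth must carry planted_probability_peak")
    mask = np.asarray(parietal_mask.data) > 0
    if not mask[tuple(truth.cluster_voxels.T)].all():
        raise ValueError("planted cluster must lie inside the mask")
    rng = np.random.default_rng(rng_seed)
    shape = parietal_mask.shape
    idx = np.indices(shape).reshape(3, -1).T
    world = parietal_mask.voxel_to_world(idx)
    d = np.linalg.norm(world - truth.true_target_world, axis=1).reshape(shape)
    bump = np.where(
        d <= 3 * hotspot_sigma_mm,
        peak * np.exp(-(d ** 2) / (2 * hotspot_sigma_mm ** 2)),
        0.0,
    )
    background = rng.uniform(0.0, background_level, size=shape) if background_level else 0.0
    data = np.where(mask, bump + background, 0.0)
    return Volume3D(data, parietal_mask.affine)


def make_toy_atlas(
    parietal_mask: Volume3D,
    n_regions: int = 6,
    rng_seed: int = 0,
    label_names: tuple[str, ...] | None = None,
) -> LabelVolume:
    """Partition the parietal mask into ``n_regions`` contiguous labels by
    seeded Voronoi growth (nearest-seed assignment on the voxel grid).

    With exactly six regions the standard left-lateral-parietal subregion
    names (PGs, PGi, PFm, PF, IP0, IP1) are used; otherwise "R1", "R2"...
    """
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    mask = np.asarray(parietal_mask.data) > 0
    idx = np.argwhere(mask)
    if n_regions > len(idx):
        raise ValueError(
            f"n_regions={n_regions} exceeds mask voxel count {len(idx)}"
        )
    rng = np.random.default_rng(rng_seed)
    seeds = idx[rng.choice(len(idx), size=n_regions, replace=False)]
    tree = cKDTree(seeds.astype(float))
    _, assign = tree.query(idx.astype(float))
    data = np.zeros(parietal_mask.shape, dtype=np.int32)
    data[tuple(idx.T)] = assign + 1
    if label_names is None:
        label_names = PARIETAL_LABELS if n_regions == 6 else tuple(
            f"R{i}" for i in range(1, n_regions + 1)
        )
    names = {i + 1: label_names[i] for i in range(n_regions)}
    return LabelVolume(data, parietal_mask.affine, names)


def make_scalp_mesh(
    semi_axes: tuple[float, float, float] = (85.0, 105.0, 80.0),
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    subdivisions: int = 3,
) -> SurfaceMesh:
    """Triangulated ellipsoid "outer skin" surface: a subdivided icosphere
    (10 * 4^n + 2 vertices) scaled by the semi-axes."""
    a, b, c = semi_axes
    if min(a, b, c) <= 0:
        raise ValueError("semi-axes must be positive")
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    vertices = ico.vertices * np.array([a, b, c]) + np.asarray(center, dtype=float)
    return SurfaceMesh(vertices, np.asarray(ico.faces))


def gamma_jitter_from_moments(mean_mm: float, sd_mm: float) -> tuple[float, float]:
    """Gamma (shape, scale) for per-subject jitter sigma_i such that the
    cohort's T1-T2 distances have the requested mean and SD.

    With d_i = sigma_i * R, R ~ chi(3): E[d] = E[sigma] * 2 sqrt(2/pi) and
    E[d^2] = 3 E[sigma^2]; matching both moments fixes the Gamma.  A
    single shared sigma forces SD/mean = sqrt(3 pi / 8 - 1) ~ 0.4220, so
    only (mean, sd) above that floor are representable.
    """
    if mean_mm <= 0 or sd_mm < 0:
        raise ValueError("need positive mean and non-negative sd")
    e_sigma = mean_mm / CHI3_MEAN_FACTOR
    e_sigma2 = (sd_mm ** 2 + mean_mm ** 2) / 3.0
    ratio = e_sigma2 / e_sigma ** 2  # = (shape + 1) / shape
    if ratio <= 1.0:
        raise ValueError(
            f"sd/mean={sd_mm / mean_mm:.4f} below the chi(3) floor "
            f"{np.sqrt(3 * np.pi / 8 - 1):.4f}; not representable"
        )
    shape = 1.0 / (ratio - 1.0)
    scale = e_sigma / shape
    return shape, scale


def make_cohort_displacements(
    cfg: CohortSimConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject (T1, T2) coordinate pairs, each (n_subjects, 3) in mm.

    T1 is fixed per subject (drawn once around ``cfg.center_world``); T2 =
    T1 + d with the components of d iid Normal(0, sigma^2), sigma taken
    from the jitter model (per-subject sigma_i drawn once when
    heterogeneous).  The T1-T2 distance is then sigma * chi(3), with mean
    ``CHI3_MEAN_FACTOR * sigma``.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    n = cfg.n_subjects
    t1 = np.asarray(cfg.center_world) + rng.normal(
        0.0, cfg.between_subject_sd, size=(n, 3)
    )
    if "fixed_sigma" in cfg.jitter_model:
        sigma = np.full(n, float(cfg.jitter_model["fixed_sigma"]))
    else:
        g = cfg.jitter_model["gamma_sigma"]
        sigma = rng.gamma(g["shape"], g["scale"], size=n)
    d = rng.normal(0.0, 1.0, size=(n, 3)) * sigma[:, None]
    return t1, t1 + d
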