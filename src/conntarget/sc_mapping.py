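"""Structural-connectivity probability maps from a toy probabilistic tracker.

The SC-guided strategy needs a per-voxel tract probability map: the number
of streamlines launched from a seed region that terminate in each cortical
voxel, normalized by the total number launched.  Production studies obtain
the count volume from a diffusion-MRI tractography tool; this module
provides (a) that normalization/ingest path and (b) a small self-contained
probabilistic tracker over an orientation field, so the whole pipeline can
be exercised and audited at desk scale.

The tracker reproduces the standard termination rules: fixed step length
(0.5 mm), a curvature threshold expressed as the minimum cosine between
successive steps (0.2), and a loop check that discards streamlines
re-entering a voxel they already visited.  Streamline accounting is exact:
terminated + exited + max-steps + curvature + loop + zero-vector equals
the number launched, asserted on every run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_io import Volume3D
from .fc_mapping import ConnectivityMap

logger = logging.getLogger("conntarget")

__all__ = [
    "OrientationField",
    "TrackerConfig",
    "TractographyResult",
    "run_toy_tractography",
    "normalize_tract_counts",
]


@dataclass
class OrientationField:
    """Unit 3-vector per voxel: data shape (nx, ny, nz, 3), world-frame."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[3] != 3:
            raise ValueError("orientation field must have shape (nx, ny, nz, 3)")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]  # type: ignore[return-value]


@dataclass
class TrackerConfig:
    """Streamline propagation parameters.

    ``n_per_seed_voxel`` defaults to the production value of 50,000
    streamlines per seed voxel; tests use a few hundred.
    ``curvature_threshold`` is the minimum allowed cosine between
    successive step directions.  ``orientation_is_axial`` treats field
    vectors as sign-free axes (the standard reading of diffusion
    orientations): at each step the sign maximizing the cosine with the
    previous step is chosen, with a random sign on the first step.  Set it
    False to follow the field's stored sign, e.g. for synthetic fields
    that deliberately reverse direction.
    """

    n_per_seed_voxel: int = 50_000
    step_mm: float = 0.5
    curvature_threshold: float = 0.2
    max_steps: int = 500
    loop_check: bool = True
    orientation_is_axial: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.step_mm <= 0:
            raise ValueError("step_mm must be positive")
        if not -1.0 <= self.curvature_threshold <= 1.0:
            raise ValueError("curvature_threshold must be in [-1, 1]")
        if self.n_per_seed_voxel < 1:
            raise ValueError("n_per_seed_voxel must be >= 1")


@dataclass
class TractographyResult:
    """Per-voxel termination counts plus exact streamline accounting."""

    counts: Volume3D
    launched_total: int
    accounting: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.accounting.values())
        if total != self.launched_total:
            raise AssertionError(
                f"streamline accounting broken: {self.accounting} sums to "
                f"{total}, launched {self.launched_total}"
            )


_FATES = ("terminated", "exited", "max_steps", "curvature", "loop", "zero_vector")


def run_toy_tractography(
    field: OrientationField,
    seed_mask: Volume3D,
    termination_mask: Volume3D,
    cfg: TrackerConfig,
    chunk_size: int = 20_000,
) -> TractographyResult:
    """Launch ``cfg.n_per_seed_voxel`` streamlines from every seed voxel.

    Each streamline starts at a uniformly random point inside its seed
    voxel and is advanced ``cfg.step_mm`` along the local orientation
    until it terminates in ``termination_mask`` (incrementing that voxel's
    count), leaves the volume, exceeds ``cfg.max_steps``, turns more
    sharply than the curvature threshold allows, or (with
    ``cfg.loop_check``) re-enters a voxel it already visited.
    """
    shape = field.shape
    if tuple(seed_mask.data.shape) != shape or tuple(termination_mask.data.shape) != shape:
        raise ValueError("masks must share the orientation field's grid")
    seed_vox = np.argwhere(np.asarray(seed_mask.data) > 0)
    if len(seed_vox) == 0:
        raise ValueError("seed mask is empty")
    term = np.asarray(termination_mask.data) > 0
    launched_total = cfg.n_per_seed_voxel * len(seed_vox)

    inv = np.linalg.inv(field.affine)
    A, b = field.affine[:3, :3], field.affine[:3, 3]
    Ai, bi = inv[:3, :3], inv[:3, 3]

    counts = np.zeros(shape, dtype=np.int64)
    acct = dict.fromkeys(_FATES, 0)
    rng = np.random.default_rng(cfg.rng_seed)

    starts_vox = np.repeat(seed_vox, cfg.n_per_seed_voxel, axis=0).astype(float)
    starts_vox += rng.uniform(-0.5, 0.5, size=starts_vox.shape)
    first_sign = rng.choice([-1.0, 1.0], size=len(starts_vox))

    for lo in range(0, len(starts_vox), chunk_size):
        hi = min(lo + chunk_size, len(starts_vox))
        _track_chunk(
            starts_vox[lo:hi] @ A.T + b,
            first_sign[lo:hi],
            field.data,
            term,
            shape,
            Ai,
            bi,
            cfg,
            counts,
            acct,
        )

    if acct["zero_vector"]:
        logger.warning(
            "%d streamlines discarded on zero orientation vectors",
            acct["zero_vector"],
        )
    return TractographyResult(Volume3D(counts, field.affine), launched_total, acct)


def _track_chunk(pos, first_sign, fdata, term, shape, Ai, bi, cfg, counts, acct):
    m = len(pos)
    shape_arr = np.array(shape)
    prev_dir = np.zeros((m, 3))
    alive = np.ones(m, dtype=bool)
    fate = np.full(m, -1, dtype=np.int8)  # index into _FATES

    def vox_of(p):
        return np.round(p @ Ai.T + bi).astype(np.int64)

    cur = vox_of(pos)
    # loop-check history of *distinct* voxels entered, per streamline
    hist = np.full((cfg.max_steps + 1, m), -1, dtype=np.int64)
    hist[0] = np.ravel_multi_index(cur.T, shape)
    hist_len = np.ones(m, dtype=np.int64)
    cur_lin = hist[0].copy()

    for step in range(cfg.max_steps):
        idx = np.where(alive)[0]
        if idx.size == 0:
            break
        v = fdata[cur[idx, 0], cur[idx, 1], cur[idx, 2]]
        norms = np.linalg.norm(v, axis=1)
        zero = norms < 1e-12
        if zero.any():
            kill = idx[zero]
            fate[kill] = _FATES.index("zero_vector")
            alive[kill] = False
            idx, v, norms = idx[~zero], v[~zero], norms[~zero]
            if idx.size == 0:
                continue
        v = v / norms[:, None]
        if step == 0:
            if cfg.orientation_is_axial:
                v = v * first_sign[idx][:, None]
        else:
            cos = np.einsum("ij,ij->i", v, prev_dir[idx])
            if cfg.orientation_is_axial:
                flip = cos < 0
                v[flip] *= -1.0
                cos = np.abs(cos)
            bad = cos < cfg.curvature_threshold
            if bad.any():
                kill = idx[bad]
                fate[kill] = _FATES.index("curvature")
                alive[kill] = False
                idx, v = idx[~bad], v[~bad]
                if idx.size == 0:
                    continue
        pos[idx] += cfg.step_mm * v
        prev_dir[idx] = v
        nvox = vox_of(pos[idx])
        outside = ((nvox < 0) | (nvox >= shape_arr)).any(axis=1)
        if outside.any():
            kill = idx[outside]
            fate[kill] = _FATES.index("exited")
            alive[kill] = False
            idx, nvox = idx[~outside], nvox[~outside]
            if idx.size == 0:
                continue
        nlin = np.ravel_multi_index(nvox.T, shape)
        hit = term[nvox[:, 0], nvox[:, 1], nvox[:, 2]]
        if hit.any():
            kill = idx[hit]
            fate[kill] = _FATES.index("terminated")
            alive[kill] = False
            np.add.at(counts, tuple(nvox[hit].T), 1)
            idx, nvox, nlin = idx[~hit], nvox[~hit], nlin[~hit]
            if idx.size == 0:
                continue
        changed = nlin != cur_lin[idx]
        if changed.any():
            cidx, clin = idx[changed], nlin[changed]
            if cfg.loop_check:
                revisit = (hist[:, cidx] == clin).any(axis=0)
                if revisit.any():
                    kill = cidx[revisit]
                    fate[kill] = _FATES.index("loop")
                    alive[kill] = False
                    cidx, clin = cidx[~revisit], clin[~revisit]
            hist[hist_len[cidx], cidx] = clin
            hist_len[cidx] += 1
            cur_lin[cidx] = clin
            cur[cidx] = np.array(np.unravel_index(clin, shape)).T
    fate[alive] = _FATES.index("max_steps")
    for i, name in enumerate(_FATES):
        acct[name] += int((fate == i).sum())


def normalize_tract_counts(
    counts: Volume3D,
    launched_total: int,
    denominator: str = "launched",
    surviving_total: int | None = None,
    seed_name: str = "hippocampal_body",
) -> ConnectivityMap:
    """Turn termination counts into a tract probability map in [0, 1].

    ``denominator="launched"`` (default) divides by the total number of
    streamlines launched from the seed, the reading of "total number of
    tracts from the seed ROI" used throughout this package;
    ``denominator="surviving"`` divides by the number that terminated in
    the target mask instead.  The same function serves the ingest path
    for precomputed count volumes: pass the tool's waytotal as
    ``launched_total``.
    """
    data = np.asarray(counts.data, dtype=float)
    if (data < 0).any():
        raise ValueError("counts must be non-negative")
    if denominator == "launched":
        denom = launched_total
    elif denominator == "surviving":
        denom = surviving_total if surviving_total is not None else int(data.sum())
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom is None or denom <= 0:
        raise ValueError(f"normalization denominator must be positive, got {denom}")
    prob = data / float(denom)
    return ConnectivityMap(
        Volume3D(prob, counts.affine),
        "SC",
        seed_name,
        meta={"denominator": denominator, "total": int(denom)},
    )
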