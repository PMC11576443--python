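"""Shared target-selection core for both connectivity strategies.

Given a connectivity map (Pearson r or tract probability), the candidate
stimulation site is found by: restricting the map to a binary parietal
mask, retaining the top decile of positive in-mask values ("cluster
thresholding at the 10th percentile"), labeling connected components,
ranking clusters, and returning the value-weighted center of gravity of
the best cluster whose depth below the scalp surface is within TMS reach
(< 30 mm by default).

Two deliberately configurable readings are exposed:

* ``top_fraction`` thresholding keeps the top 10 % of positive in-mask
  values (``mode="top"``); the literal alternative of discarding only the
  bottom 10 % is available as ``mode="discard_bottom"``.
* clusters are ranked by value-weighted mass (``rank_by="mass"``); peak
  value ranking is available as ``rank_by="peak"``.

Both choices are recorded in the returned target's metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import ceil

import numpy as np
from scipy import ndimage

from .core_io import SurfaceMesh, Volume3D
from .fc_mapping import ConnectivityMap

logger = logging.getLogger("conntarget")

__all__ = [
    "Cluster",
    "ClusterSet",
    "TargetCoordinate",
    "apply_mask",
    "percentile_threshold",
    "label_clusters",
    "scalp_depth",
    "rank_and_select",
    "select_target",
]


@dataclass
class Cluster:
    id: int
    voxel_indices: np.ndarray  # (k, 3) int
    mass: float  # sum of original map values
    cog_world: np.ndarray  # value-weighted center of gravity, mm
    peak_value: float


@dataclass
class ClusterSet:
    """Labeled suprathreshold connected components of a connectivity map."""

    labels: Volume3D  # integer labels, 0 = background
    clusters: list[Cluster]
    connectivity: int = 26

    def __post_init__(self) -> None:
        ids = [c.id for c in self.clusters]
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("cluster ids must be contiguous from 1")
        for c in self.clusters:
            if not c.mass > 0:
                raise ValueError(f"cluster {c.id} has non-positive mass")


@dataclass
class TargetCoordinate:
    """A world-space stimulation site with its selection context."""

    world: np.ndarray  # mm
    depth_mm: float
    cluster_rank: int
    strategy: str
    reachable: bool
    subregion: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.world = np.asarray(self.world, dtype=float)
        if self.depth_mm < 0:
            raise ValueError("depth must be non-negative")


def apply_mask(cmap: ConnectivityMap, mask: Volume3D) -> ConnectivityMap:
    """Zero the map outside a binary mask (values inside are unchanged)."""
    if tuple(cmap.map.shape) != tuple(mask.shape) or not np.allclose(
        cmap.map.affine, mask.affine
    ):
        raise ValueError("mask grid does not match the connectivity map")
    m = np.asarray(mask.data) > 0
    if not m.any():
        raise ValueError("mask is empty")
    data = np.where(m, cmap.map.data, 0.0)
    return ConnectivityMap(
        Volume3D(data, cmap.map.affine), cmap.strategy, cmap.seed_name,
        meta=dict(cmap.meta),
    )


def percentile_threshold(
    cmap: ConnectivityMap,
    mask: Volume3D | None = None,
    top_fraction: float = 0.10,
    mode: str = "top",
) -> Volume3D:
    """Binary volume of the in-mask voxels surviving the decile cut.

    ``mode="top"`` keeps the positive in-mask voxels whose value is at or
    above the (1 - top_fraction) quantile of positive in-mask values, i.e.
    ceil(top_fraction * P) voxels plus any ties at the cut.
    ``mode="discard_bottom"`` instead removes the bottom ``top_fraction``
    of positive values.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    data = np.asarray(cmap.map.data, dtype=float)
    inside = np.ones(data.shape, dtype=bool) if mask is None else np.asarray(mask.data) > 0
    pos = inside & (data > 0)
    p = int(pos.sum())
    if p == 0:
        raise ValueError("no positive in-mask voxels to threshold")
    vals = np.sort(data[pos])[::-1]
    if mode == "top":
        k = ceil(top_fraction * p)
        thr = vals[k - 1]
    elif mode == "discard_bottom":
        thr = float(np.quantile(data[pos], top_fraction))
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    binary = pos & (data >= thr)
    return Volume3D(binary.astype(np.uint8), cmap.map.affine)


_STRUCTURES = {6: 1, 18: 2, 26: 3}


def label_clusters(
    binary: Volume3D,
    cmap: ConnectivityMap,
    connectivity: int = 26,
) -> ClusterSet:
    """Connected components of a binary volume, with mass and COG taken
    from the original map values.

    ``connectivity`` is 6 (faces), 18 (faces+edges) or 26 (faces+edges+
    corners); 26 is the common neuroimaging default.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    b = np.asarray(binary.data) > 0
    if not b.any():
        raise ValueError("binary volume is empty")
    structure = ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])
    lab, n = ndimage.label(b, structure=structure)
    vol = cmap.map
    clusters: list[Cluster] = []
    for cid in range(1, n + 1):
        idx = np.argwhere(lab == cid)
        vals = vol.data[tuple(idx.T)].astype(float)
        mass = float(vals.sum())
        world = vol.voxel_to_world(idx)
        cog = (vals[:, None] * world).sum(axis=0) / mass
        clusters.append(
            Cluster(cid, idx, mass, cog, float(vals.max()))
        )
    return ClusterSet(Volume3D(lab, vol.affine), clusters, connectivity)


def scalp_depth(point: np.ndarray, mesh: SurfaceMesh, method: str = "vertex") -> float:
    """Distance (mm) from a point to the scalp surface.

    ``method="vertex"`` (default) is the minimum Euclidean distance to any
    mesh vertex — the discrete sampling used when the surface stands in
    for "each voxel in the outer skin".  ``method="surface"`` computes the
    exact point-to-triangle distance for refined meshes.
    """
    point = np.asarray(point, dtype=float)
    if mesh.n_vertices == 0:
        raise ValueError("mesh has no vertices")
    if method == "vertex":
        return float(np.min(np.linalg.norm(mesh.vertices - point, axis=1)))
    if method == "surface":
        if len(mesh.faces) == 0:
            raise ValueError("mesh has no faces")
        closest = _closest_points_on_triangles(
            point,
            mesh.vertices[mesh.faces[:, 0]],
            mesh.vertices[mesh.faces[:, 1]],
            mesh.vertices[mesh.faces[:, 2]],
        )
        return float(np.min(np.linalg.norm(closest - point, axis=1)))
    raise ValueError(f"unknown depth method {method!r}")


def _closest_points_on_triangles(p, a, b, c):
    """Closest point to ``p`` on each triangle (a_i, b_i, c_i).

    Barycentric region classification (Ericson, Real-Time Collision
    Detection), vectorized over triangles.
    """
    ab, ac = b - a, c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = d1 / (d1 - d3)
        t_ac = d2 / (d2 - d6)
        t_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        denom = va + vb + vc
        v = vb / denom
        w = vc / denom

    out = a + v[:, None] * ab + w[:, None] * ac  # face interior
    on_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    out = np.where(on_bc[:, None], b + np.nan_to_num(t_bc)[:, None] * (c - b), out)
    on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    out = np.where(on_ac[:, None], a + np.nan_to_num(t_ac)[:, None] * ac, out)
    on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    out = np.where(on_ab[:, None], a + np.nan_to_num(t_ab)[:, None] * ab, out)
    out = np.where(((d6 >= 0) & (d5 <= d6))[:, None], c, out)
    out = np.where(((d3 >= 0) & (d4 <= d3))[:, None], b, out)
    out = np.where(((d1 <= 0) & (d2 <= 0))[:, None], a, out)
    return out


def rank_and_select(
    clusters: ClusterSet,
    mesh: SurfaceMesh,
    max_depth: float = 30.0,
    strategy: str = "FC",
    rank_by: str = "mass",
    depth_method: str = "vertex",
) -> TargetCoordinate:
    """Pick the stimulation coordinate from a ranked cluster list.

    Clusters are sorted by mass descending (ties: larger peak value, then
    lower id; ``rank_by="peak"`` swaps the first two keys).  Walking down
    the ranking, the first cluster whose COG lies closer than ``max_depth``
    to the scalp wins.  If no cluster is reachable the minimum-depth
    cluster is returned with ``reachable=False`` and a warning.
    """
    if not clusters.clusters:
        raise ValueError("empty cluster set")
    if rank_by == "mass":
        key = lambda c: (-c.mass, -c.peak_value, c.id)
    elif rank_by == "peak":
        key = lambda c: (-c.peak_value, -c.mass, c.id)
    else:
        raise ValueError(f"unknown rank_by {rank_by!r}")
    ranked = sorted(clusters.clusters, key=key)
    depths = [scalp_depth(c.cog_world, mesh, depth_method) for c in ranked]
    meta = {"rank_by": rank_by, "coordinate": "value-weighted cluster COG",
            "max_depth_mm": max_depth, "n_clusters": len(ranked)}
    for rank, (c, d) in enumerate(zip(ranked, depths), start=1):
        if d < max_depth:
            return TargetCoordinate(c.cog_world, d, rank, strategy, True, meta=meta)
    best = int(np.argmin(depths))
    logger.warning(
        "no cluster within %.1f mm of the scalp; returning minimum-depth "
        "cluster (%.1f mm) as unreachable", max_depth, depths[best]
    )
    return TargetCoordinate(
        ranked[best].cog_world, depths[best], best + 1, strategy, False, meta=meta
    )


def select_target(
    cmap: ConnectivityMap,
    parietal_mask: Volume3D,
    mesh: SurfaceMesh,
    max_depth: float = 30.0,
    top_fraction: float = 0.10,
    connectivity: int = 26,
    rank_by: str = "mass",
    threshold_mode: str = "top",
    depth_method: str = "vertex",
) -> TargetCoordinate:
    """Full selection pipeline: mask -> decile threshold -> cluster ->
    rank -> depth-constrained coordinate."""
    masked = apply_mask(cmap, parietal_mask)
    binary = percentile_threshold(masked, parietal_mask, top_fraction, threshold_mode)
    clusters = label_clusters(binary, masked, connectivity)
    target = rank_and_select(
        clusters, mesh, max_depth, cmap.strategy, rank_by, depth_method
    )
    target.meta.update({"top_fraction": top_fraction, "connectivity": connectivity,
                        "threshold_mode": threshold_mode})
    return target
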