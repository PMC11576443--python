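"""Volumetric containers, coordinate bookkeeping, and file round-trips.

Everything downstream (connectivity mapping, tractography, target
selection) operates on the types defined here.  Conventions:

* voxel indices are 0-based; a voxel's world position is its **center**;
* world coordinates are continuous millimetres in RAS+;
* the world position of voxel index ``v`` is ``affine @ [v, 1]``.

Volumes are stored as NIfTI-1, confound tables as TSV, surface meshes as
ASCII OFF (or GIFTI), affines as 4x4 whitespace-delimited text.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import nibabel as nib
import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .reproducibility_stats import ReproducibilityReport

logger = logging.getLogger("conntarget")

__all__ = [
    "Volume3D",
    "TimeSeries4D",
    "LabelVolume",
    "SurfaceMesh",
    "AffineTransform",
    "read_volume",
    "write_volume",
    "read_atlas",
    "read_confounds",
    "read_mesh",
    "write_mesh",
    "read_affine",
    "write_affine",
    "write_report",
]


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular (non-invertible spatial part)")
    return affine


@dataclass
class Volume3D:
    """Scalar field on a regular 3-D grid with a voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D needs 3-D data, got ndim={self.data.ndim}")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Per-axis voxel spacing in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices (..., 3) to world mm."""
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        """Map world-mm points (..., 3) to continuous voxel indices."""
        pts = np.asarray(pts, dtype=float)
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def same_grid(self, other: "Volume3D | TimeSeries4D") -> bool:
        return self.shape[:3] == tuple(other.data.shape[:3]) and np.allclose(
            self.affine, other.affine
        )


@dataclass
class TimeSeries4D:
    """BOLD-like 4-D array (x, y, z, t) with affine and repetition time."""

    data: np.ndarray
    affine: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"TimeSeries4D needs 4-D data, got ndim={self.data.ndim}")
        if self.data.shape[3] < 2:
            raise ValueError("time axis must have length >= 2")
        if not self.tr > 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def spatial_volume(self, t: int = 0) -> Volume3D:
        return Volume3D(self.data[..., t], self.affine)


@dataclass
class LabelVolume:
    """Integer-labeled parcellation; 0 is background."""

    data: np.ndarray
    affine: np.ndarray
    label_names: dict[int, str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("LabelVolume needs 3-D data")
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.allclose(self.data, np.round(self.data)):
                raise ValueError("label data must be integer-valued")
            self.data = np.round(self.data).astype(np.int32)
        if self.data.min() < 0:
            raise ValueError("labels must be non-negative (0 = background)")
        self.affine = _check_affine(self.affine)
        present = set(np.unique(self.data)) - {0}
        missing = present - set(self.label_names)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        return Volume3D.voxel_to_world(self, idx)  # type: ignore[arg-type]

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        return Volume3D.world_to_voxel(self, pts)  # type: ignore[arg-type]


@dataclass
class SurfaceMesh:
    """Triangulated surface: vertices (N, 3) world mm, faces (M, 3) indices."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (N, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (M, 3)")
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@dataclass
class AffineTransform:
    """A 4x4 world-to-world (mm -> mm) affine, e.g. native -> MNI."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("transform must be 4x4")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("transform is singular")

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path) -> Volume3D | TimeSeries4D:
    """Read a NIfTI-1 file into :class:`Volume3D` (3-D) or :class:`TimeSeries4D` (4-D).

    The repetition time of a 4-D series is taken from the header's fourth
    zoom (seconds).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    affine = img.affine
    if data.ndim == 3:
        return Volume3D(data, affine)
    if data.ndim == 4:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
        return TimeSeries4D(data, affine, tr=tr)
    raise ValueError(f"expected 3-D or 4-D image, got ndim={data.ndim}")


def write_volume(vol: Volume3D | TimeSeries4D | LabelVolume, path: str | Path) -> Path:
    """Write a volume or 4-D series to NIfTI-1 (TR stored in the 4th zoom)."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32)
                          if not isinstance(vol, LabelVolume)
                          else np.asarray(vol.data, dtype=np.int16),
                          vol.affine)
    if isinstance(vol, TimeSeries4D):
        zooms = list(img.header.get_zooms())
        zooms[3] = vol.tr
        img.header.set_zooms(zooms)
        img.header["xyzt_units"] = 10  # mm + sec
    nib.save(img, str(path))
    return path


def read_atlas(path: str | Path, label_names: dict[int, str] | str | Path) -> LabelVolume:
    """Read an integer parcellation plus its label-name table (dict or JSON file)."""
    vol = read_volume(path)
    if isinstance(vol, TimeSeries4D):
        raise ValueError("atlas must be a 3-D volume")
    if not isinstance(label_names, dict):
        with open(label_names) as fh:
            label_names = {int(k): v for k, v in json.load(fh).items()}
    return LabelVolume(vol.data, vol.affine, label_names)


def read_confounds(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated confound table: one column per regressor, one
    row per timepoint."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] == 0:
        raise ValueError("confound table has no columns")
    return df


def read_mesh(path: str | Path) -> SurfaceMesh:
    """Read a surface mesh from ASCII OFF or GIFTI."""
    path = Path(path)
    if path.suffix.lower() == ".gii" or str(path).endswith(".surf.gii"):
        img = nib.load(str(path))
        vertices = img.agg_data("pointset")
        faces = img.agg_data("triangle")
        return SurfaceMesh(vertices, faces)
    return _read_off(path)


def _read_off(path: Path) -> SurfaceMesh:
    with open(path) as fh:
        tokens: list[str] = []
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                tokens.extend(line.split())
    if not tokens or tokens[0] != "OFF":
        raise ValueError(f"{path}: not an OFF file")
    nv, nf = int(tokens[1]), int(tokens[2])
    pos = 4
    vertices = np.array(tokens[pos : pos + 3 * nv], dtype=float).reshape(nv, 3)
    pos += 3 * nv
    faces = np.empty((nf, 3), dtype=np.int64)
    for i in range(nf):
        k = int(tokens[pos])
        if k != 3:
            raise ValueError("only triangular OFF faces are supported")
        faces[i] = [int(t) for t in tokens[pos + 1 : pos + 4]]
        pos += 1 + k
    return SurfaceMesh(vertices, faces)


def write_mesh(mesh: SurfaceMesh, path: str | Path) -> Path:
    """Write a mesh as ASCII OFF."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{len(mesh.vertices)} {len(mesh.faces)} 0\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
    return path


def read_affine(path: str | Path) -> AffineTransform:
    """Read a 4x4 whitespace-delimited affine from text."""
    mat = np.loadtxt(path)
    return AffineTransform(mat)


def write_affine(xfm: AffineTransform, path: str | Path) -> Path:
    np.savetxt(path, xfm.matrix, fmt="%.12g")
    return Path(path)


# ---------------------------------------------------------------------------
# report output
# ---------------------------------------------------------------------------

def write_report(report: "ReproducibilityReport", out_dir: str | Path) -> dict[str, Path]:
    """Write a reproducibility report as a set of plain-text files.

    Emits ``targets.csv`` (one row per subject x strategy x timepoint),
    ``group_stats.json`` (group moments, Welch test, Shapiro-Wilk,
    inter-strategy separation, stability fractions) and one
    ``stability_<strategy>.csv`` matrix per strategy when a subregion
    analysis was performed.
    """
    if report.n_subjects == 0:
        raise ValueError("empty report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    targets_path = out_dir / "targets.csv"
    report.targets.to_csv(targets_path, index=False)
    files["targets"] = targets_path

    stats_path = out_dir / "group_stats.json"
    with open(stats_path, "w") as fh:
        json.dump(report.group_stats_dict(), fh, indent=2)
    files["group_stats"] = stats_path

    if report.stability is not None:
        for strat, stab in report.stability.items():
            p = out_dir / f"stability_{strat}.csv"
            stab["matrix"].to_csv(p)
            files[f"stability_{strat}"] = p
    logger.info("report written to %s (%d files)", out_dir, len(files))
    return files
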