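"""Test-retest reproducibility analysis of stimulation targets.

Given per-subject target coordinates for two strategies (SC- and
FC-guided) at two timepoints, this module transforms them to MNI space,
computes intra-individual Euclidean distances (T1 vs T2), checks
normality with Shapiro-Wilk, compares the two strategies with Welch's
unequal-variance t-test, measures the SC-FC separation per timepoint, and
summarizes how often each subject's target stays in the same atlas
subregion across timepoints (stability matrices and their diagonal
fraction).

Welch's t and Shapiro-Wilk W are implemented here directly (Welch-
Satterthwaite degrees of freedom; Royston's 1995 approximation for the W
null), with p-values taken from the corresponding reference
distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats as _sps
from scipy.spatial import cKDTree

from .core_io import AffineTransform, LabelVolume

__all__ = [
    "CohortTargets",
    "ReproducibilityReport",
    "to_mni",
    "euclidean_distance",
    "welch_t_test",
    "shapiro_wilk",
    "assign_subregion",
    "stability_matrix",
    "compare_strategies",
]

STRATEGIES = ("SC", "FC")
TIMEPOINTS = ("T1", "T2")


def to_mni(coord: np.ndarray, xfm: AffineTransform) -> np.ndarray:
    """Map a native-space coordinate (mm) to MNI space through a 4x4 affine."""
    coord = np.asarray(coord, dtype=float)
    return xfm.apply(coord)


def euclidean_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance in mm between two world coordinates."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("coordinates must be finite")
    return float(np.linalg.norm(a - b))


def welch_t_test(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Welch's unequal-variance two-sample t-test (two-sided).

    t = (mean(x) - mean(y)) / sqrt(sx^2/nx + sy^2/ny), with
    Welch-Satterthwaite degrees of freedom; the p-value comes from the
    Student-t survival function.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least 2 observations")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return {"t": 0.0, "df": float(nx + ny - 2), "p": 1.0}
        raise ValueError("both groups have zero variance")
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * _sps.t.sf(abs(t), df)
    return {"t": float(t), "df": float(df), "p": float(p)}


def _shapiro_weights(n: int) -> np.ndarray:
    """Royston (1995) coefficient vector a for the W statistic."""
    if n == 3:
        return np.array([-np.sqrt(0.5), 0.0, np.sqrt(0.5)])
    m = _sps.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    ssm = float(m @ m)
    c = m / np.sqrt(ssm)
    rsn = 1.0 / np.sqrt(n)
    a = np.empty(n)
    a_n = (-2.706056 * rsn**5 + 4.434685 * rsn**4 - 2.071190 * rsn**3
           - 0.147981 * rsn**2 + 0.221157 * rsn + c[-1])
    if n > 5:
        a_n1 = (-3.582633 * rsn**5 + 5.682633 * rsn**4 - 1.752461 * rsn**3
                - 0.293762 * rsn**2 + 0.042981 * rsn + c[-2])
        phi = (ssm - 2 * m[-1]**2 - 2 * m[-2]**2) / (1 - 2 * a_n**2 - 2 * a_n1**2)
        a[2:-2] = m[2:-2] / np.sqrt(phi)
        a[-1], a[-2] = a_n, a_n1
        a[0], a[1] = -a_n, -a_n1
    else:
        phi = (ssm - 2 * m[-1]**2) / (1 - 2 * a_n**2)
        a[1:-1] = m[1:-1] / np.sqrt(phi)
        a[-1] = a_n
        a[0] = -a_n
    return a


def shapiro_wilk(x: np.ndarray) -> dict[str, float]:
    """Shapiro-Wilk normality test, W and its approximate null p-value.

    W = (sum a_i x_(i))^2 / sum (x - mean)^2 with Royston's coefficient
    approximation; the p-value uses the exact arcsine form at n = 3 and
    Royston's normalizing transformations of 1 - W for 4 <= n <= 5000.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    if n < 3 or n > 5000:
        raise ValueError(f"n={n} out of supported range [3, 5000]")
    ss = float(((x - x.mean()) ** 2).sum())
    if ss == 0:
        raise ValueError("all observations are identical")
    a = _shapiro_weights(n)
    W = float((a @ x) ** 2 / ss)
    W = min(W, 1.0)
    if n == 3:
        p = 6.0 / np.pi * (np.arcsin(np.sqrt(W)) - np.arcsin(np.sqrt(0.75)))
        p = float(np.clip(p, 0.0, 1.0))
    elif n <= 11:
        g = -2.273 + 0.459 * n
        mu = 0.5440 - 0.39978 * n + 0.025054 * n**2 - 0.0006714 * n**3
        sig = np.exp(1.3822 - 0.77857 * n + 0.062767 * n**2 - 0.0020322 * n**3)
        if W == 1.0:
            p = 1.0
        elif 1.0 - W >= np.exp(g):  # W too small for the log-log transform
            p = 0.0
        else:
            z = (-np.log(g - np.log(1.0 - W)) - mu) / sig
            p = float(_sps.norm.sf(z))
    else:
        u = np.log(n)
        mu = -1.5861 - 0.31082 * u - 0.083751 * u**2 + 0.0038915 * u**3
        sig = np.exp(-0.4803 - 0.082676 * u + 0.0030302 * u**2)
        if W == 1.0:
            p = 1.0
        else:
            z = (np.log(1.0 - W) - mu) / sig
            p = float(_sps.norm.sf(z))
    return {"W": W, "p": p}


def assign_subregion(
    coord: np.ndarray, atlas: LabelVolume, max_snap_mm: float = 6.0
) -> str:
    """Atlas label of the voxel containing a world coordinate.

    A coordinate falling on background (label 0) is snapped to the nearest
    labeled voxel within ``max_snap_mm``; beyond that it is "unassigned".
    """
    coord = np.asarray(coord, dtype=float)
    vox = np.round(atlas.world_to_voxel(coord)).astype(int)
    if (vox < 0).any() or (vox >= np.asarray(atlas.shape)).any():
        raise ValueError(f"coordinate {coord} outside the atlas volume")
    label = int(atlas.data[tuple(vox)])
    if label != 0:
        return atlas.label_names[label]
    nz = np.argwhere(atlas.data > 0)
    if len(nz) == 0:
        return "unassigned"
    tree = cKDTree(atlas.voxel_to_world(nz))
    dist, i = tree.query(coord)
    if dist <= max_snap_mm:
        return atlas.label_names[int(atlas.data[tuple(nz[i])])]
    return "unassigned"


def stability_matrix(
    labels_t1: list[str], labels_t2: list[str]
) -> dict[str, Any]:
    """Region-by-region contingency of per-subject T1 vs T2 subregion
    labels, and the fraction of subjects on the diagonal (same subregion
    at both timepoints)."""
    if len(labels_t1) != len(labels_t2):
        raise ValueError("label lists must have equal length")
    n = len(labels_t1)
    regions = sorted(set(labels_t1) | set(labels_t2))
    mat = pd.DataFrame(0, index=regions, columns=regions, dtype=int)
    for r1, r2 in zip(labels_t1, labels_t2):
        mat.loc[r1, r2] += 1
    diag = int(sum(mat.loc[r, r] for r in regions))
    return {"matrix": mat, "diagonal_fraction": diag / n if n else 0.0}


@dataclass
class CohortTargets:
    """Target coordinates for every subject x strategy x timepoint cell.

    ``coords`` has shape (n_subjects, 2, 2, 3): strategy axis ordered
    (SC, FC), timepoint axis ordered (T1, T2), coordinates in mm.
    Optional per-cell scalp depths (mm) travel with the coordinates into
    the written report.
    """

    subjects: list[str]
    coords: np.ndarray
    depths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.subjects)
        if self.coords.shape != (n, 2, 2, 3):
            raise ValueError(
                f"coords must have shape ({n}, 2, 2, 3), got {self.coords.shape}"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError("all coordinates must be finite")
        if self.depths is not None:
            self.depths = np.asarray(self.depths, dtype=float)
            if self.depths.shape != (n, 2, 2):
                raise ValueError("depths must have shape (n, 2, 2)")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @classmethod
    def from_pairs(
        cls,
        sc_t1: np.ndarray, sc_t2: np.ndarray,
        fc_t1: np.ndarray, fc_t2: np.ndarray,
        subjects: list[str] | None = None,
    ) -> "CohortTargets":
        """Build a cohort from four (n, 3) coordinate arrays."""
        arrs = [np.asarray(a, dtype=float) for a in (sc_t1, sc_t2, fc_t1, fc_t2)]
        n = len(arrs[0])
        coords = np.stack(
            [np.stack(arrs[:2], axis=1), np.stack(arrs[2:], axis=1)], axis=1
        )
        subjects = subjects or [f"sub-{i + 1:03d}" for i in range(n)]
        return cls(subjects, coords)


@dataclass
class ReproducibilityReport:
    """Everything the reproducibility analysis produces."""

    subjects: list[str]
    intra_distances: dict[str, np.ndarray]  # per strategy, (n,) mm
    group_stats: dict[str, dict[str, float]]  # per strategy: mean, sd
    welch: dict[str, float] | str  # or "insufficient n"
    shapiro: dict[str, dict[str, float] | None]
    inter_strategy: dict[str, Any]  # per-timepoint arrays + pooled mean/sd
    targets: pd.DataFrame  # one row per subject x strategy x timepoint
    stability: dict[str, dict[str, Any]] | None = None
    subregion_counts: dict[str, dict[str, int]] | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def group_stats_dict(self) -> dict:
        """JSON-serializable summary used by ``core_io.write_report``."""
        out: dict[str, Any] = {
            "n_subjects": self.n_subjects,
            "group_stats": self.group_stats,
            "welch": self.welch,
            "shapiro": self.shapiro,
            "inter_strategy": {
                "pooled_mean": self.inter_strategy["pooled_mean"],
                "pooled_sd": self.inter_strategy["pooled_sd"],
            },
            "coordinate_definition": self.meta.get(
                "coordinate_definition", "value-weighted cluster COG"
            ),
        }
        if self.stability is not None:
            out["stability"] = {
                s: {
                    "diagonal_fraction": st["diagonal_fraction"],
                    "diagonal_percent": int(round(100 * st["diagonal_fraction"])),
                }
                for s, st in self.stability.items()
            }
        if self.subregion_counts is not None:
            out["subregion_counts"] = self.subregion_counts
        return out


def compare_strategies(
    cohort: CohortTargets,
    atlas: LabelVolume | None = None,
    mni_xfm: AffineTransform | None = None,
) -> ReproducibilityReport:
    """Run the full group analysis on a two-strategy, two-timepoint cohort.

    Coordinates are first mapped to MNI space (identity if no transform is
    given), then per-strategy intra-individual T1-T2 distances, Shapiro-
    Wilk normality, Welch's t across strategies, per-timepoint SC-FC
    separations (pooled over subjects and timepoints), and — when an atlas
    is supplied — subregion assignments, occurrence histograms over the
    2n occurrences per strategy, and T1-vs-T2 stability matrices.
    """
    n = cohort.n_subjects
    if n == 0:
        raise ValueError("empty cohort")
    xfm = mni_xfm or AffineTransform.identity()
    coords = xfm.apply(cohort.coords.reshape(-1, 3)).reshape(cohort.coords.shape)

    intra = {
        s: np.linalg.norm(coords[:, si, 1] - coords[:, si, 0], axis=1)
        for si, s in enumerate(STRATEGIES)
    }
    group_stats = {
        s: {
            "mean": float(d.mean()),
            "sd": float(d.std(ddof=1)) if n > 1 else float("nan"),
        }
        for s, d in intra.items()
    }
    shapiro = {
        s: (shapiro_wilk(d) if 3 <= n <= 5000 and np.ptp(d) > 0 else None)
        for s, d in intra.items()
    }
    welch: dict[str, float] | str
    if n >= 2:
        try:
            welch = welch_t_test(intra["SC"], intra["FC"])
        except ValueError as exc:  # e.g. both strategies fully degenerate
            welch = f"undefined: {exc}"
    else:
        welch = "insufficient n"

    inter_tp = {
        tp: np.linalg.norm(coords[:, 0, ti] - coords[:, 1, ti], axis=1)
        for ti, tp in enumerate(TIMEPOINTS)
    }
    pooled = np.concatenate(list(inter_tp.values()))
    inter = {
        **inter_tp,
        "pooled_mean": float(pooled.mean()),
        "pooled_sd": float(pooled.std(ddof=1)) if len(pooled) > 1 else float("nan"),
    }

    stability = None
    subregion_counts = None
    labels = np.full((n, 2, 2), None, dtype=object)
    if atlas is not None:
        for i in range(n):
            for si in range(2):
                for ti in range(2):
                    labels[i, si, ti] = assign_subregion(coords[i, si, ti], atlas)
        stability = {
            s: stability_matrix(list(labels[:, si, 0]), list(labels[:, si, 1]))
            for si, s in enumerate(STRATEGIES)
        }
        subregion_counts = {
            s: {
                str(k): int(v)
                for k, v in pd.Series(labels[:, si, :].ravel())
                .value_counts()
                .sort_index()
                .items()
            }
            for si, s in enumerate(STRATEGIES)
        }

    rows = []
    for i, sub in enumerate(cohort.subjects):
        for si, s in enumerate(STRATEGIES):
            for ti, tp in enumerate(TIMEPOINTS):
                rows.append(
                    {
                        "subject": sub,
                        "strategy": s,
                        "timepoint": tp,
                        "x": coords[i, si, ti, 0],
                        "y": coords[i, si, ti, 1],
                        "z": coords[i, si, ti, 2],
                        "depth_mm": (
                            cohort.depths[i, si, ti]
                            if cohort.depths is not None
                            else float("nan")
                        ),
                        "subregion": labels[i, si, ti],
                    }
                )
    targets = pd.DataFrame(rows)

    return ReproducibilityReport(
        subjects=list(cohort.subjects),
        intra_distances=intra,
        group_stats=group_stats,
        welch=welch,
        shapiro=shapiro,
        inter_strategy=inter,
        targets=targets,
        stability=stability,
        subregion_counts=subregion_counts,
        meta={"coordinate_definition": "value-weighted cluster COG",
              "mni_transform": "affine" if mni_xfm is not None else "identity"},
    )
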