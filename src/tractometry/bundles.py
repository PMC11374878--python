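"""Atlas-based bundle labeling, density-mask volumetry and tract means.

Labeling follows the centroid-distance rule: every streamline is compared
to each atlas centroid with the flip-symmetrized maximum corresponding-
point distance (both resampled to the same point count); among the tracts
whose distance threshold it satisfies, the streamline is assigned to the
closest one, otherwise it stays unlabeled.  Each streamline belongs to at
most one tract, so labels partition the tractogram.

Per-tract morphometry measures the density-mask volume (voxels crossed by
at least ``min_fibers`` distinct streamlines) and normalizes it to total
brain volume and white-matter volume.  Microstructural tract means pool
the trilinearly interpolated map values at every streamline point after
0.1 mm resampling (point-weighted, so longer streamlines weigh more).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .dti import ScalarMap
from .tracking import Tractogram

__all__ = [
    "BundleEntry",
    "BundleAtlas",
    "LabeledTractogram",
    "UNLABELED",
    "resample_streamline",
    "streamline_distance",
    "label_tractogram",
    "density_mask",
    "bundle_volume",
    "normalize_volume",
    "tract_metric_mean",
    "measure_subject",
]

UNLABELED = "UNLABELED"
METRIC_NAMES = ("fa", "md", "ad", "rd", "gfa", "ndi", "iwvf", "odi")


@dataclass
class BundleEntry:
    name: str
    centroid: np.ndarray  # (K, 3) atlas/world mm
    threshold_mm: float = 10.0
    category: str = "other"  # association | projection | interhemispheric | other
    hemisphere: str = ""

    def __post_init__(self):
        self.centroid = np.asarray(self.centroid, dtype=float).reshape(-1, 3)
        if self.threshold_mm <= 0:
            raise ValueError("distance threshold must be positive")


@dataclass
class BundleAtlas:
    entries: list[BundleEntry]

    def __post_init__(self):
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("atlas labels must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def transformed(self, matrix: np.ndarray) -> "BundleAtlas":
        """Apply a rigid/affine 4x4 matrix (atlas -> subject mm)."""
        matrix = np.asarray(matrix, dtype=float)
        out = []
        for e in self.entries:
            c = e.centroid @ matrix[:3, :3].T + matrix[:3, 3]
            out.append(BundleEntry(e.name, c, e.threshold_mm, e.category, e.hemisphere))
        return BundleAtlas(out)


@dataclass
class LabeledTractogram:
    tractogram: Tractogram
    labels: np.ndarray  # str per streamline, UNLABELED allowed

    def bundle(self, name: str) -> list[np.ndarray]:
        return [s for s, l in zip(self.tractogram.streamlines, self.labels) if l == name]

    def counts(self) -> dict[str, int]:
        uniq, cnt = np.unique(self.labels, return_counts=True)
        return dict(zip(uniq.tolist(), cnt.tolist()))


def resample_streamline(s: np.ndarray, step: float | None = None, n_points: int | None = None) -> np.ndarray:
    """Equidistant arc-length resampling, preserving both endpoints.

    Give either a target ``step`` (mm; the actual spacing is the largest
    value <= step that divides the arc length evenly) or an exact
    ``n_points``.
    """
    s = np.asarray(s, dtype=float)
    if s.ndim != 2 or s.shape[0] < 2:
        raise ValueError("streamline needs at least two points")
    seg = np.linalg.norm(np.diff(s, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        raise ValueError("zero-length streamline cannot be resampled")
    if (step is None) == (n_points is None):
        raise ValueError("specify exactly one of step, n_points")
    if n_points is None:
        if step <= 0:
            raise ValueError("step must be positive")
        n_points = int(np.ceil(total / step)) + 1
    if n_points < 2:
        raise ValueError("need at least two output points")
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0.0, total, n_points)
    out = np.empty((n_points, 3))
    for k in range(3):
        out[:, k] = np.interp(t, arc, s[:, k])
    return out


def streamline_distance(a: np.ndarray, b: np.ndarray, n_points: int | None = 21) -> float:
    """Flip-symmetrized maximum corresponding-point distance (mm).

    Both inputs are resampled to ``n_points`` unless ``n_points`` is None,
    in which case they must already share a point count.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if n_points is not None:
        a = resample_streamline(a, n_points=n_points)
        b = resample_streamline(b, n_points=n_points)
    elif a.shape[0] != b.shape[0]:
        raise ValueError(f"point counts differ ({a.shape[0]} vs {b.shape[0]})")
    direct = np.linalg.norm(a - b, axis=1).max()
    flipped = np.linalg.norm(a - b[::-1], axis=1).max()
    return float(min(direct, flipped))


def label_tractogram(t: Tractogram, atlas: BundleAtlas, n_points: int = 21) -> LabeledTractogram:
    """Assign each streamline to its closest below-threshold atlas tract."""
    if len(atlas) == 0:
        raise ValueError("atlas has no entries")
    cents = np.stack([resample_streamline(e.centroid, n_points=n_points) for e in atlas.entries])
    thresholds = np.array([e.threshold_mm for e in atlas.entries])
    names = np.array(atlas.names + [UNLABELED], dtype=object)
    if len(t) == 0:
        return LabeledTractogram(t, np.empty(0, dtype=object))
    lines = np.stack([resample_streamline(s, n_points=n_points) for s in t.streamlines])
    # (S, C): flip-symmetrized max corresponding-point distance
    diff = lines[:, None, :, :] - cents[None, :, :, :]
    d_direct = np.linalg.norm(diff, axis=-1).max(axis=-1)
    diff_f = lines[:, None, :, :] - cents[None, :, ::-1, :]
    d_flip = np.linalg.norm(diff_f, axis=-1).max(axis=-1)
    dist = np.minimum(d_direct, d_flip)
    within = dist <= thresholds[None, :]
    masked = np.where(within, dist, np.inf)
    best = np.argmin(masked, axis=1)
    best = np.where(np.isfinite(masked[np.arange(len(best)), best]), best, len(atlas))
    return LabeledTractogram(t, names[best])


def density_mask(
    bundle: list[np.ndarray],
    shape: tuple[int, int, int],
    affine: np.ndarray,
    min_fibers: int = 5,
    resample_step: float | None = None,
) -> np.ndarray:
    """Voxels crossed by at least ``min_fibers`` distinct streamlines.

    A streamline contributes at most once per voxel regardless of how many
    of its points fall inside.  ``resample_step`` optionally resamples
    streamlines first (pass a value <= the voxel size to guarantee no
    voxel is skipped between consecutive points).
    """
    if min_fibers < 1:
        raise ValueError("min_fibers must be >= 1")
    inv = np.linalg.inv(affine)
    counts = np.zeros(shape, dtype=np.int32)
    dims = np.array(shape)
    for s in bundle:
        if resample_step is not None:
            s = resample_streamline(s, step=resample_step)
        vox = np.round(np.asarray(s, float) @ inv[:3, :3].T + inv[:3, 3]).astype(int)
        ok = np.all((vox >= 0) & (vox < dims), axis=1)
        vox = vox[ok]
        if vox.shape[0] == 0:
            continue
        flat = np.unique((vox[:, 0] * shape[1] + vox[:, 1]) * shape[2] + vox[:, 2])
        counts.ravel()[flat] += 1
    return counts >= min_fibers


def bundle_volume(mask: np.ndarray, voxel_size: float) -> float:
    """Mask volume in cm^3 for isotropic voxels of ``voxel_size`` mm."""
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    return float(mask.sum()) * voxel_size**3 / 1000.0


def normalize_volume(raw_cm3: float, reference_cm3: float) -> float:
    """Volume as a percentage of a reference volume."""
    if reference_cm3 <= 0:
        raise ValueError("reference volume must be positive")
    return 100.0 * raw_cm3 / reference_cm3


def tract_metric_mean(
    bundle: list[np.ndarray],
    scalar_map: ScalarMap | np.ndarray,
    affine: np.ndarray,
    resample_step: float = 0.1,
    record_normality: dict | None = None,
) -> float:
    """Point-weighted mean of a quantitative map over a bundle.

    Every streamline is resampled to ``resample_step`` mm and the map is
    trilinearly interpolated at every point; the mean pools all points of
    all streamlines.  A Shapiro-Wilk normality p-value over (up to 500 of)
    the pooled values is recorded in ``record_normality`` when a dict is
    passed; it never gates the mean.
    """
    data = scalar_map.data if isinstance(scalar_map, ScalarMap) else np.asarray(scalar_map)
    if not bundle:
        return float("nan")
    inv = np.linalg.inv(affine)
    dims = np.array(data.shape)
    pooled = []
    for s in bundle:
        pts = resample_streamline(s, step=resample_step)
        vox = pts @ inv[:3, :3].T + inv[:3, 3]
        if np.any(vox < -0.5) or np.any(vox > dims - 0.5):
            bad = vox[np.any((vox < -0.5) | (vox > dims - 0.5), axis=1)][0]
            raise ValueError(
                f"streamline point at voxel coordinate {np.round(bad, 2)} "
                f"falls outside the map grid {tuple(data.shape)}"
            )
        pooled.append(ndimage.map_coordinates(data, vox.T, order=1, mode="nearest"))
    vals = np.concatenate(pooled)
    if record_normality is not None:
        sub = vals[:: max(1, len(vals) // 500)]
        if len(sub) >= 3 and np.ptp(sub) > 0:
            record_normality["shapiro_p"] = float(stats.shapiro(sub).pvalue)
        else:
            record_normality["shapiro_p"] = float("nan")
    return float(vals.mean())


@dataclass
class SubjectMeasures:
    """Per-subject tract table plus the global normalization volumes."""

    subject_id: str
    sex: str
    tbv_cm3: float
    wmv_cm3: float
    per_tract: pd.DataFrame  # one row per atlas label

    def to_frame(self) -> pd.DataFrame:
        df = self.per_tract.copy()
        df.insert(0, "subject_id", self.subject_id)
        df.insert(1, "sex", self.sex)
        df["tbv_cm3"] = self.tbv_cm3
        df["wmv_cm3"] = self.wmv_cm3
        return df


def measure_subject(
    labeled: LabeledTractogram,
    maps: dict[str, ScalarMap],
    brain_mask: np.ndarray,
    wm_mask: np.ndarray,
    affine: np.ndarray,
    voxel_size: float,
    atlas: BundleAtlas,
    subject_id: str = "subject",
    sex: str = "",
    min_fibers: int = 5,
    metric_resample_mm: float = 0.1,
) -> SubjectMeasures:
    """All per-tract measures for one subject.

    TBV and WMV come from the mask voxel counts; per tract: density-mask
    volume (raw cm^3, %TBV, %WMV) and the mean of each quantitative map.
    Absent bundles get volume 0 and NaN metric means.
    """
    if brain_mask.shape != wm_mask.shape:
        raise ValueError("brain and WM masks must share a grid")
    for m in maps.values():
        if m.data.shape != brain_mask.shape:
            raise ValueError(f"map {m.name!r} grid differs from the masks")
    tbv = bundle_volume(brain_mask, voxel_size)
    wmv = bundle_volume(wm_mask, voxel_size)
    rows = []
    for entry in atlas.entries:
        bundle = labeled.bundle(entry.name)
        row = {"tract": entry.name, "category": entry.category, "n_streamlines": len(bundle)}
        if bundle:
            dm = density_mask(bundle, brain_mask.shape, affine, min_fibers=min_fibers)
            vol = bundle_volume(dm, voxel_size)
        else:
            vol = 0.0
        row["volume_cm3"] = vol
        row["vol_pct_tbv"] = normalize_volume(vol, tbv)
        row["vol_pct_wmv"] = normalize_volume(vol, wmv) if wmv > 0 else float("nan")
        for name in METRIC_NAMES:
            if name in maps and bundle:
                row[name] = tract_metric_mean(
                    bundle, maps[name], affine, resample_step=metric_resample_mm
                )
            else:
                row[name] = float("nan")
        rows.append(row)
    return SubjectMeasures(subject_id, sex, tbv, wmv, pd.DataFrame(rows))
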