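"""Lesion ROI placement and aggregation on parameter maps.

The measurement protocol places three planar circular ROIs per lesion
(1.0-2.5 cm^2 each) on the largest viable cross-section, excluding necrotic
tissue, and reports the average of the three ROI means per marker together
with the lesion's maximum diameter.  Placement is automatic here: an
exact Euclidean distance transform of the viable region (lesion minus
necrosis) yields every feasible circle centre, and three well-separated
centres are chosen deterministically for a given seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.spatial import ConvexHull

from .models import ParameterMaps

AREA_BOUNDS_CM2 = (1.0, 2.5)
MARKERS = ("adc", "md", "mk")


@dataclass(frozen=True)
class CircularROI:
    """One planar circular ROI: in-plane centre (mm), radius (mm), slice."""

    center_mm: tuple[float, float]
    radius_mm: float
    slice_index: int

    @property
    def area_cm2(self) -> float:
        return float(np.pi * self.radius_mm**2 / 100.0)


@dataclass(frozen=True)
class ROISet:
    """Exactly three distinct circular ROIs on one lesion."""

    rois: tuple[CircularROI, CircularROI, CircularROI]
    spacing: tuple[float, ...]
    protocol_deviation: bool = False  # area below the 1.0 cm^2 protocol floor

    def __post_init__(self) -> None:
        if len(self.rois) != 3:
            raise ValueError("an ROI set holds exactly 3 ROIs")
        centers = {(r.center_mm, r.slice_index) for r in self.rois}
        if len(centers) != 3:
            raise ValueError("ROIs must sit at three different positions")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "spacing_mm": list(self.spacing),
            "protocol_deviation": self.protocol_deviation,
            "rois": [
                {
                    "center_mm": list(r.center_mm),
                    "radius_mm": r.radius_mm,
                    "slice_index": r.slice_index,
                    "area_cm2": r.area_cm2,
                }
                for r in self.rois
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ROISet":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        rois = tuple(
            CircularROI(tuple(r["center_mm"]), r["radius_mm"], r["slice_index"])
            for r in payload["rois"]
        )
        return cls(rois=rois, spacing=tuple(payload["spacing_mm"]),
                   protocol_deviation=payload["protocol_deviation"])


@dataclass(frozen=True)
class LesionMeasurement:
    """Per-marker triple of ROI means, their average, and lesion diameter."""

    roi_means: dict[str, tuple[float, float, float]]
    means: dict[str, float]
    diameter_cm: float
    protocol_deviation: bool = False


def _as_slices(mask: np.ndarray) -> np.ndarray:
    """View a 2-D (planar) or 3-D mask as (x, y, n_slices)."""
    return mask[..., np.newaxis] if mask.ndim == 2 else mask


def place_rois(
    lesion_mask: np.ndarray,
    necrosis_mask: np.ndarray | None,
    spacing: tuple[float, ...],
    area_bounds_cm2: tuple[float, float] = AREA_BOUNDS_CM2,
    seed: int | None = None,
) -> ROISet:
    """Select three circular ROIs inside the viable lesion tissue.

    The common radius is the largest allowed by the area window that still
    admits three distinct centres fully inside lesion-minus-necrosis (per
    the distance transform).  If even the smallest protocol area (1.0 cm^2)
    does not fit, the radius shrinks to the largest feasible one and the
    set is flagged as a protocol deviation.  Centres are chosen greedily
    for spread; exact ties are broken by the seeded RNG.
    """
    lesion = np.asarray(lesion_mask, dtype=bool)
    necrosis = (
        np.zeros_like(lesion) if necrosis_mask is None else np.asarray(necrosis_mask, bool)
    )
    if necrosis.shape != lesion.shape:
        raise ValueError("necrosis mask shape differs from lesion mask")
    viable = lesion & ~necrosis
    if not viable.any():
        raise ValueError("no viable lesion tissue: necrosis covers the lesion")

    in_plane = tuple(spacing[:2])
    stack = _as_slices(viable)
    edt = np.zeros(stack.shape, dtype=float)
    for z in range(stack.shape[2]):
        if stack[:, :, z].any():
            edt[:, :, z] = distance_transform_edt(stack[:, :, z], sampling=in_plane)

    flat_order = np.argsort(edt, axis=None)[::-1]
    vals = edt.reshape(-1)[flat_order]
    if np.count_nonzero(vals) < 3:
        raise ValueError("viable region too small to host three distinct ROIs")

    r_low = float(np.sqrt(area_bounds_cm2[0] * 100.0 / np.pi))
    r_high = float(np.sqrt(area_bounds_cm2[1] * 100.0 / np.pi))
    radius = min(r_high, float(vals[2]))  # 3rd-largest EDT guarantees 3 centres
    deviation = radius < r_low

    cand_flat = np.flatnonzero(edt.reshape(-1) >= radius - 1e-9)
    coords = np.column_stack(np.unravel_index(cand_flat, edt.shape)).astype(float)
    pos_mm = np.column_stack(
        [(coords[:, 0] + 0.5) * in_plane[0], (coords[:, 1] + 0.5) * in_plane[1], coords[:, 2]]
    )
    cand_edt = edt.reshape(-1)[cand_flat]

    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    # first centre: deepest point (seeded tie-break)
    best = np.flatnonzero(cand_edt >= cand_edt.max() - 1e-12)
    chosen.append(int(rng.choice(best)))
    while len(chosen) < 3:
        sel = pos_mm[chosen]
        same_slice = pos_mm[:, 2][:, None] == sel[:, 2][None, :]
        d2 = np.where(
            same_slice,
            (pos_mm[:, 0][:, None] - sel[:, 0][None, :]) ** 2
            + (pos_mm[:, 1][:, None] - sel[:, 1][None, :]) ** 2,
            np.inf,
        )
        score = d2.min(axis=1)
        score[chosen] = -np.inf
        best = np.flatnonzero(score >= score.max() - 1e-12)
        chosen.append(int(rng.choice(best)))

    rois = tuple(
        CircularROI(
            center_mm=(float(pos_mm[i, 0]), float(pos_mm[i, 1])),
            radius_mm=float(radius),
            slice_index=int(pos_mm[i, 2]),
        )
        for i in chosen
    )
    return ROISet(rois=rois, spacing=tuple(spacing), protocol_deviation=deviation)


def roi_voxel_mask(roi: CircularROI, grid_shape: tuple[int, ...], spacing) -> np.ndarray:
    """Boolean voxel mask of one planar ROI on the map grid."""
    planar = len(grid_shape) == 2
    nx, ny = grid_shape[:2]
    xs = (np.arange(nx) + 0.5) * spacing[0]
    ys = (np.arange(ny) + 0.5) * spacing[1]
    # strictly-inside membership (with a relative epsilon against fp
    # round-trip): with centre EDT >= r every member voxel then lies inside
    # the viable region, since the nearest non-viable voxel sits at distance
    # exactly >= r
    plane = (
        (xs[:, None] - roi.center_mm[0]) ** 2 + (ys[None, :] - roi.center_mm[1]) ** 2
        < roi.radius_mm**2 * (1.0 - 1e-9)
    )
    if planar:
        return plane
    mask = np.zeros(grid_shape, dtype=bool)
    mask[:, :, roi.slice_index] = plane
    return mask


def lesion_max_diameter_cm(lesion_mask: np.ndarray, spacing) -> float:
    """Maximum caliper extent of the lesion mask, in cm.

    Computed as the largest centre-to-centre distance between mask voxels
    (via the convex hull) plus one mean voxel pitch for the voxel extent.
    """
    lesion = np.asarray(lesion_mask, dtype=bool)
    pts = np.column_stack(np.nonzero(lesion)).astype(float)
    if pts.shape[0] == 0:
        raise ValueError("empty lesion mask")
    pts_mm = pts * np.asarray(spacing, dtype=float)
    pitch = float(np.mean(spacing))
    if pts.shape[0] == 1:
        return pitch / 10.0
    try:
        hull_pts = pts_mm[ConvexHull(pts_mm).vertices]
    except Exception:  # degenerate (collinear) point sets
        hull_pts = pts_mm
    d2 = ((hull_pts[:, None, :] - hull_pts[None, :, :]) ** 2).sum(-1)
    return float((np.sqrt(d2.max()) + pitch) / 10.0)


def extract_measurement(
    maps: ParameterMaps,
    rois: ROISet,
    lesion_mask: np.ndarray,
) -> LesionMeasurement:
    """ROI means per marker (average of the three ROI means) plus diameter.

    Each ROI mean uses only voxels with a valid fit for that marker; an ROI
    whose voxels are all invalid raises.
    """
    grid = maps.shape
    roi_means: dict[str, list[float]] = {m: [] for m in MARKERS}
    for idx, roi in enumerate(rois.rois):
        vox = roi_voxel_mask(roi, grid, maps.spacing)
        for marker in MARKERS:
            values = getattr(maps, marker)[vox]
            values = values[np.isfinite(values)]
            if values.size == 0:
                raise ValueError(f"ROI {idx} contains no valid voxels for {marker}")
            roi_means[marker].append(float(values.mean()))
    means = {m: float(np.mean(roi_means[m])) for m in MARKERS}
    return LesionMeasurement(
        roi_means={m: tuple(v) for m, v in roi_means.items()},
        means=means,
        diameter_cm=lesion_max_diameter_cm(lesion_mask, maps.spacing),
        protocol_deviation=rois.protocol_deviation,
    )
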