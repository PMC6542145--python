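"""NIfTI-1 input/output for signal stacks and parameter maps."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .models import ParameterMaps

MAP_SUFFIXES = {"adc": "_ADC", "md": "_MD", "mk": "_MK", "s0": "_S0"}
VALID_SUFFIX = "_valid"


def _affine(spacing: tuple[float, ...]) -> np.ndarray:
    aff = np.eye(4)
    for i, s in enumerate(spacing[:3]):
        aff[i, i] = s
    return aff


def _to_3d(arr: np.ndarray) -> np.ndarray:
    """Planar (2-D) grids are written as single-slice 3-D volumes."""
    return arr[..., np.newaxis] if arr.ndim == 2 else arr


def save_volume(path: str | Path, data: np.ndarray, spacing: tuple[float, ...]) -> None:
    """Write a 3-D volume or 4-D multi-b stack as NIfTI-1."""
    arr = np.asarray(data, dtype=np.float64)
    if arr.ndim == 2:  # planar image (x, y) -> single-slice volume
        arr = arr[:, :, np.newaxis]
    elif arr.ndim == 3 and len(spacing) == 2:  # planar stack (x, y, b)
        arr = arr[:, :, np.newaxis, :]
    img = nib.Nifti1Image(arr, _affine(tuple(spacing) + (1.0,) * (3 - len(spacing))))
    nib.save(img, str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj, dtype=np.float64), spacing


def save_parameter_maps(maps: ParameterMaps, out_dir: str | Path, prefix: str) -> list[Path]:
    """One NIfTI per parameter (suffixes _ADC/_MD/_MK/_S0) plus a _valid mask."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spacing = tuple(maps.spacing) + (1.0,) * (3 - len(maps.spacing))
    written = []
    for attr, suffix in MAP_SUFFIXES.items():
        p = out_dir / f"{prefix}{suffix}.nii"
        nib.save(nib.Nifti1Image(_to_3d(getattr(maps, attr)), _affine(spacing)), str(p))
        written.append(p)
    p = out_dir / f"{prefix}{VALID_SUFFIX}.nii"
    nib.save(
        nib.Nifti1Image(_to_3d(maps.valid).astype(np.uint8), _affine(spacing)), str(p)
    )
    written.append(p)
    return written


def load_parameter_maps(map_dir: str | Path, prefix: str, planar: bool = False) -> ParameterMaps:
    map_dir = Path(map_dir)
    arrays = {}
    spacing: tuple[float, ...] = (1.0, 1.0, 1.0)
    for attr, suffix in MAP_SUFFIXES.items():
        img = nib.load(str(map_dir / f"{prefix}{suffix}.nii"))
        arr = np.asarray(img.dataobj, dtype=np.float64)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        arrays[attr] = arr
    valid = np.asarray(
        nib.load(str(map_dir / f"{prefix}{VALID_SUFFIX}.nii")).dataobj
    ).astype(bool)
    if planar:
        arrays = {k: v[..., 0] for k, v in arrays.items()}
        valid = valid[..., 0]
        spacing = spacing[:2]
    return ParameterMaps(
        s0=arrays["s0"], md=arrays["md"], mk=arrays["mk"], adc=arrays["adc"],
        valid=valid, spacing=spacing,
    )
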