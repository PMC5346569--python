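"""NIfTI and FSL-dialect text I/O.

Volumes are NIfTI-1 (.nii or .nii.gz, gzip handled transparently by
nibabel).  Stage-1 timecourses use the FSL ``dr_stage1_subject#####.txt``
dialect: whitespace-delimited text, one row per timepoint, one column per
component.  Voxel flattening always goes through :mod:`dualreg.core`.
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import (
    BOLDDataset,
    SpatialMapSet,
    SubjectMapSet,
    TimecourseMatrix,
    VolumeGrid,
    flatten_volumes,
    unflatten_volumes,
)

__all__ = [
    "read_4d_image",
    "read_bold",
    "read_template_maps",
    "write_4d_image",
    "read_mask",
    "write_stage1_text",
    "read_stage1_text",
    "stage1_filename",
    "stage2_filename",
]


def stage1_filename(idx: int) -> str:
    """FSL dual_regression stage-1 text file name for subject ``idx``."""
    return f"dr_stage1_subject{idx:05d}.txt"


def stage2_filename(idx: int) -> str:
    """FSL dual_regression stage-2 image file name for subject ``idx``."""
    return f"dr_stage2_subject{idx:05d}.nii.gz"


def _load_4d(path, mask_path=None):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    img = nib.load(str(path))
    arr = np.asarray(img.get_fdata(), dtype=float)
    if arr.ndim == 3:
        arr = arr[..., np.newaxis]
    if arr.ndim != 4:
        raise ValueError(f"{path}: expected a 3-D or 4-D image, got {arr.ndim}-D")
    zooms = img.header.get_zooms()[:3]
    grid = VolumeGrid(dims=arr.shape[:3], voxel_size=zooms, affine=img.affine)
    mask = None
    if mask_path is not None:
        mpath = Path(mask_path)
        if not mpath.exists():
            raise FileNotFoundError(f"mask not found: {mpath}")
        mask = np.asarray(nib.load(str(mpath)).get_fdata()) > 0
        if mask.shape != arr.shape[:3]:
            raise ValueError(
                f"mask dimensions {mask.shape} do not match image dimensions {arr.shape[:3]}"
            )
    flat = flatten_volumes(arr, mask=mask)
    bad = ~np.isfinite(flat)
    if bad.any():
        v, t = np.argwhere(bad)[0]
        raise ValueError(f"{path}: non-finite value at flattened voxel {v}, volume {t}")
    return flat, grid, mask


def read_bold(path, mask: "os.PathLike | str | None" = None, tr: float | None = None,
              subject_id: str = "") -> BOLDDataset:
    """Read a 4-D BOLD image into an N voxels x T timepoints dataset."""
    flat, grid, mask_arr = _load_4d(path, mask)
    if tr is None:
        img = nib.load(str(path))
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return BOLDDataset(data=flat, grid=grid, tr=tr, subject_id=subject_id, mask=mask_arr)


def read_template_maps(path, mask: "os.PathLike | str | None" = None,
                       component_names: list[str] | None = None) -> SpatialMapSet:
    """Read a 4-D template image (one volume per component) into a map set."""
    flat, grid, mask_arr = _load_4d(path, mask)
    return SpatialMapSet(maps=flat.T, grid=grid, mask=mask_arr,
                         component_names=component_names)


def read_4d_image(path, mask=None, kind: str = "bold", **kw):
    """Read a 4-D NIfTI as either a BOLD dataset or a template map set.

    ``kind`` is ``"bold"`` or ``"maps"``; the fourth image axis is time for
    the former and the component index for the latter.
    """
    if kind == "bold":
        return read_bold(path, mask=mask, **kw)
    if kind == "maps":
        return read_template_maps(path, mask=mask, **kw)
    raise ValueError(f"kind must be 'bold' or 'maps', got {kind!r}")


def write_4d_image(obj, path) -> None:
    """Write a map set or BOLD dataset back to a float32 NIfTI-1 file.

    Out-of-mask voxels are written as zero.  Component/time order is
    preserved, so a read/write roundtrip reproduces the data to float32
    precision.
    """
    if isinstance(obj, SpatialMapSet):
        flat, grid, mask = obj.maps.T, obj.grid, obj.mask
    elif isinstance(obj, (BOLDDataset, SubjectMapSet)):
        flat, grid, mask = obj.data, obj.grid, obj.mask
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    vol = unflatten_volumes(np.asarray(flat, dtype=np.float32), grid.dims, mask=mask)
    img = nib.Nifti1Image(vol, affine=grid.affine)
    img.header.set_zooms((*grid.voxel_size, 1.0) if vol.ndim == 4 else grid.voxel_size)
    path = Path(path)
    try:
        nib.save(img, str(path))
    except OSError as exc:
        raise OSError(f"cannot write image to {path}: {exc}") from exc


def read_mask(path) -> np.ndarray:
    """Read a 3-D mask image as a boolean volume (nonzero = in mask)."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"mask not found: {p}")
    return np.asarray(nib.load(str(p)).get_fdata()) > 0


def write_stage1_text(tc: TimecourseMatrix, path) -> None:
    """Write stage-1 timecourses as T rows x M columns of plain text."""
    if tc.n_components < 1 or tc.n_timepoints < 1:
        raise ValueError("timecourse matrix must be at least 1x1")
    np.savetxt(str(path), tc.data.T, fmt="%.8g", delimiter=" ")


def read_stage1_text(path, tr: float = 1.0, subject_id: str = "") -> TimecourseMatrix:
    """Read an FSL-dialect stage-1 text file back into a timecourse matrix.

    Amplitudes are recomputed from the stored rows (they are not carried in
    the text format), so the result is always ``normalized=False`` with
    amplitudes equal to the row standard deviations as read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stage-1 text file not found: {path}")
    rows: list[list[float]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            toks = line.split()
            if not toks:
                continue
            try:
                rows.append([float(t) for t in toks])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-numeric token") from exc
    if not rows:
        raise ValueError(f"{path}: empty stage-1 text file")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError(f"{path}: ragged rows (expected {width} columns)")
    data = np.asarray(rows, dtype=float).T  # stored T x M, we carry M x T
    sd = data.std(axis=1, ddof=1)
    if np.any(sd <= 0):
        raise ValueError(f"{path}: constant timecourse column(s) {np.flatnonzero(sd <= 0).tolist()}")
    return TimecourseMatrix(data=data, amplitudes=sd, tr=tr, subject_id=subject_id)
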