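"""Shared data model for dual-regression analyses.

All spatial data are carried as 2-D matrices over a flattened voxel axis.
The flattening convention is fixed package-wide: the first image axis is
fastest-varying (Fortran order), i.e. voxel ``(i, j, k)`` of a volume with
dimensions ``(X, Y, Z)`` lands at flat index ``i + X*j + X*Y*k``.  A single
pair of routines (:func:`flatten_volumes`, :func:`unflatten_volumes`) is the
only authority for this ordering; every reader, writer and simulator goes
through them so that template maps and BOLD data can never be silently
misaligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VolumeGrid",
    "SpatialMapSet",
    "BOLDDataset",
    "TimecourseMatrix",
    "SubjectMapSet",
    "ResidualSummary",
    "flatten_volumes",
    "unflatten_volumes",
]


@dataclass(frozen=True)
class VolumeGrid:
    """Geometry of a 3-D sampling grid.

    Parameters
    ----------
    dims : tuple of int
        Number of voxels along each of the three axes.
    voxel_size : tuple of float
        Voxel edge lengths in millimetres.
    affine : (4, 4) ndarray
        Voxel-to-world transform.  Passed through to file headers untouched;
        all in-package coordinates are 0-based voxel indices.
    """

    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        dims = tuple(int(d) for d in self.dims)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise ValueError(f"dims must be three positive integers, got {self.dims}")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be three positive lengths, got {self.voxel_size}")
        affine = self.affine
        if affine is None:
            affine = np.diag([*vs, 1.0])
        affine = np.asarray(affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "voxel_size", vs)
        object.__setattr__(self, "affine", affine)

    @property
    def n_voxels(self) -> int:
        """Total voxel count of the unmasked grid."""
        x, y, z = self.dims
        return x * y * z

    def compatible_with(self, other: "VolumeGrid") -> bool:
        return self.dims == other.dims


def flatten_volumes(vol: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Flatten a 3-D or 4-D array to (N, V) with the package voxel order.

    ``vol`` has shape (X, Y, Z) or (X, Y, Z, V); the spatial axes are
    collapsed with the first axis fastest-varying.  If ``mask`` (boolean,
    shape (X, Y, Z)) is given, only in-mask voxels are kept, in the same
    order.  Returns shape (N,) for 3-D input, (N, V) for 4-D input.
    """
    vol = np.asarray(vol)
    if vol.ndim == 3:
        flat = vol.reshape(-1, order="F")
    elif vol.ndim == 4:
        n = vol.shape[0] * vol.shape[1] * vol.shape[2]
        flat = vol.reshape((n, vol.shape[3]), order="F")
    else:
        raise ValueError(f"expected 3-D or 4-D array, got {vol.ndim}-D")
    if mask is not None:
        mask_flat = np.asarray(mask, dtype=bool).reshape(-1, order="F")
        if mask_flat.size != (flat.shape[0] if flat.ndim > 0 else 0):
            raise ValueError("mask shape does not match volume shape")
        flat = flat[mask_flat]
    return flat


def unflatten_volumes(
    flat: np.ndarray,
    dims: tuple[int, int, int],
    mask: np.ndarray | None = None,
    fill: float = 0.0,
) -> np.ndarray:
    """Inverse of :func:`flatten_volumes`.

    ``flat`` has shape (N,) or (N, V); out-of-mask voxels are set to
    ``fill``.  Returns shape (X, Y, Z) or (X, Y, Z, V).
    """
    flat = np.asarray(flat)
    n_total = int(np.prod(dims))
    vshape: tuple[int, ...]
    if flat.ndim == 1:
        full = np.full(n_total, fill, dtype=flat.dtype)
        vshape = tuple(dims)
    elif flat.ndim == 2:
        full = np.full((n_total, flat.shape[1]), fill, dtype=flat.dtype)
        vshape = (*dims, flat.shape[1])
    else:
        raise ValueError("flat array must be 1-D or 2-D")
    if mask is None:
        if flat.shape[0] != n_total:
            raise ValueError(f"expected {n_total} voxels, got {flat.shape[0]}")
        full[...] = flat
    else:
        mask_flat = np.asarray(mask, dtype=bool).reshape(-1, order="F")
        if mask_flat.size != n_total:
            raise ValueError("mask shape does not match grid dims")
        if int(mask_flat.sum()) != flat.shape[0]:
            raise ValueError("flat array length does not match mask voxel count")
        full[mask_flat] = flat
    return full.reshape(vshape, order="F")


def _check_n(n: int, grid: VolumeGrid, mask: np.ndarray | None, what: str) -> None:
    expected = int(np.asarray(mask, bool).sum()) if mask is not None else grid.n_voxels
    if n != expected:
        raise ValueError(f"{what}: voxel axis has length {n}, but grid/mask selects {expected}")


@dataclass
class SpatialMapSet:
    """A set of template network maps, M components x N voxels.

    Maps are used unthresholded; the scale of each map is common to all
    subjects and therefore cancels in group comparisons.
    """

    maps: np.ndarray
    grid: VolumeGrid
    mask: np.ndarray | None = None
    component_names: list[str] | None = None

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2:
            raise ValueError("maps must be 2-D (M components x N voxels)")
        m, n = self.maps.shape
        if m < 1:
            raise ValueError("need at least one component")
        _check_n(n, self.grid, self.mask, "SpatialMapSet")
        zero = ~np.any(self.maps != 0, axis=1)
        if zero.any():
            raise ValueError(f"all-zero component map(s): {np.flatnonzero(zero).tolist()}")
        if self.component_names is None:
            self.component_names = [f"IC{i}" for i in range(m)]
        if len(self.component_names) != m:
            raise ValueError("component_names length must equal number of components")

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.maps.shape[1]


@dataclass
class BOLDDataset:
    """One subject's 4-D BOLD data as an N voxels x T timepoints matrix."""

    data: np.ndarray
    grid: VolumeGrid
    tr: float = 1.0
    subject_id: str = ""
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (N voxels x T timepoints)")
        _check_n(self.data.shape[0], self.grid, self.mask, "BOLDDataset")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class TimecourseMatrix:
    """Stage-1 network timecourses, M components x T timepoints.

    ``amplitudes`` holds the per-component timecourse standard deviation
    (the a_i placed on the diagonal of A) measured *before* any
    normalization; after design normalization every row has unit standard
    deviation but the original amplitudes are retained here.
    """

    data: np.ndarray
    amplitudes: np.ndarray
    tr: float = 1.0
    normalized: bool = False
    subject_id: str = ""
    component_names: list[str] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (M x T)")
        m = self.data.shape[0]
        if self.amplitudes.shape != (m,):
            raise ValueError("amplitudes must have one entry per component")
        if np.any(self.amplitudes <= 0):
            bad = np.flatnonzero(self.amplitudes <= 0).tolist()
            raise ValueError(f"non-positive amplitude for component(s) {bad}")
        if self.normalized:
            sd = self.data.std(axis=1, ddof=1)
            if not np.allclose(sd, 1.0, atol=1e-10):
                raise ValueError("normalized timecourses must have unit standard deviation")

    @property
    def n_components(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class SubjectMapSet:
    """Stage-2 subject-specific spatial maps, N voxels x M components.

    ``design_normalized`` distinguishes raw coefficient maps (False) from
    semi-standardized maps computed with unit-variance stage-1 timecourses
    (True).  Only the latter carry network-amplitude information and are
    valid for group-level inference in the presence of amplitude effects.
    """

    data: np.ndarray
    grid: VolumeGrid
    design_normalized: bool = True
    subject_id: str = ""
    mask: np.ndarray | None = None
    component_names: list[str] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (N voxels x M components)")
        _check_n(self.data.shape[0], self.grid, self.mask, "SubjectMapSet")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("subject maps contain non-finite values")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_components(self) -> int:
        return self.data.shape[1]


@dataclass
class ResidualSummary:
    """Residual scale summaries from the two regression stages.

    stage1_resid_std is the per-timepoint spatial residual standard
    deviation of the stage-1 fit; stage2_resid_std is the per-voxel
    temporal residual standard deviation of the stage-2 fit (the
    estimation analogue of the simulator's noise std map).
    """

    stage1_resid_std: np.ndarray | None = None
    stage2_resid_std: np.ndarray | None = None

    def __post_init__(self):
        for name in ("stage1_resid_std", "stage2_resid_std"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if np.any(v < 0):
                    raise ValueError(f"{name} must be nonnegative")
                setattr(self, name, v)
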