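"""Two-stage dual regression with optional design normalization.

Given a set of template network maps S (M x N) and one subject's BOLD data
Y (N x T), stage 1 solves the multivariate spatial regression

    Y = S' B_tc + E1      =>      B_tc = pinv(S') Y        (M x T)

giving one network timecourse per template map, each reflecting the average
signal over the map's voxels after partialling out the other networks.
Stage 2 regresses those timecourses back into the same data temporally,

    Y' = B_tc' B_sm + E2  =>      B_sm = Y pinv(B_tc)      (N x M)

yielding the subject-specific spatial maps.  The stage-1 timecourses have
subject-specific amplitudes a_i = std(timecourse); dividing each row by its
amplitude before stage 2 ("design normalization") produces semi-standardized
coefficients B_sm* = Y pinv(A^-1 B_tc) whose units are signal change per
unit standard deviation of the network timecourse.  B_sm* — and only
B_sm* — carries network-amplitude information and correctly localizes
within-network amplitude effects, so it is the default group-level
statistic here; raw B_sm maps are produced only on explicit request.

Both stages mean-center the data and the regressors by default (no
intercept column), the established convention for this procedure; it makes
the coefficients invariant to voxelwise mean offsets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .core import (
    BOLDDataset,
    ResidualSummary,
    SpatialMapSet,
    SubjectMapSet,
    TimecourseMatrix,
)
from .io import read_bold, stage1_filename, stage2_filename, write_4d_image, write_stage1_text

logger = logging.getLogger(__name__)

__all__ = [
    "stage1",
    "stage2",
    "compute_amplitudes",
    "normalize_design",
    "run_dual_regression",
    "DualRegression",
    "DualRegressionResults",
]


def _check_rank(design: np.ndarray, names: list[str] | None, stage: str) -> np.ndarray:
    """SVD-based rank check; returns the pseudoinverse of ``design``.

    Singular values below max(design.shape) * eps * s_max are treated as
    zero.  Rank deficiency is an error (naming the most collinear
    components) rather than a silent minimum-norm solution, because pinv on
    collinear templates mislocalizes connectivity.
    """
    u, s, vt = np.linalg.svd(design, full_matrices=False)
    tol = max(design.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    m = design.shape[1]
    if rank < m:
        # components loading most heavily on the null-space directions
        null_load = np.abs(vt[rank:]).sum(axis=0)
        bad = np.argsort(null_load)[::-1][: (m - rank + 1)]
        labels = [names[i] if names else str(i) for i in sorted(bad.tolist())]
        raise np.linalg.LinAlgError(
            f"{stage}: design is rank-deficient (rank {rank} < {m}); "
            f"collinear component(s): {labels}"
        )
    s_inv = np.where(s > tol, 1.0 / s, 0.0)
    return (vt.T * s_inv) @ u.T


def stage1(y: BOLDDataset, s: SpatialMapSet, demean: bool = True) -> TimecourseMatrix:
    """Spatial regression of the template maps into one subject's data.

    Returns the M x T least-squares timecourses with per-component
    amplitudes (row standard deviations) filled in and ``normalized=False``.
    """
    if y.n_voxels != s.n_voxels:
        raise ValueError(
            f"voxel count mismatch: data has {y.n_voxels}, templates have {s.n_voxels}"
        )
    if y.n_voxels < s.n_components + 2:
        raise ValueError("too few voxels for the number of components")
    design = s.maps.T.copy()  # N x M
    data = y.data
    if demean:
        design -= design.mean(axis=0, keepdims=True)
        data = data - data.mean(axis=1, keepdims=True)
    pinv = _check_rank(design, s.component_names, "stage 1")
    b_tc = pinv @ data  # M x T
    amplitudes = compute_amplitudes_raw(b_tc, s.component_names)
    return TimecourseMatrix(
        data=b_tc,
        amplitudes=amplitudes,
        tr=y.tr,
        normalized=False,
        subject_id=y.subject_id,
        component_names=list(s.component_names) if s.component_names else None,
    )


def compute_amplitudes_raw(rows: np.ndarray, names: list[str] | None = None) -> np.ndarray:
    """Sample standard deviation (divisor T-1) of each demeaned row."""
    rows = np.asarray(rows, dtype=float)
    sd = (rows - rows.mean(axis=1, keepdims=True)).std(axis=1, ddof=1)
    if np.any(sd <= 0):
        bad = np.flatnonzero(sd <= 0)
        labels = [names[i] if names else str(i) for i in bad.tolist()]
        raise ValueError(
            f"constant timecourse for component(s) {labels}: zero amplitude is not normalizable"
        )
    return sd


def compute_amplitudes(tc: TimecourseMatrix) -> np.ndarray:
    """Per-component timecourse amplitudes a_i = std of each row."""
    return compute_amplitudes_raw(tc.data, tc.component_names)


def normalize_design(tc: TimecourseMatrix) -> TimecourseMatrix:
    """Divide each stage-1 timecourse by its standard deviation.

    Returns A^-1 B_tc with every row at unit standard deviation; the
    original amplitudes are retained in ``amplitudes``.  Idempotent.
    """
    if tc.normalized:
        return tc
    a = compute_amplitudes(tc)
    return TimecourseMatrix(
        data=tc.data / a[:, np.newaxis],
        amplitudes=tc.amplitudes,
        tr=tc.tr,
        normalized=True,
        subject_id=tc.subject_id,
        component_names=tc.component_names,
    )


def stage2(
    y: BOLDDataset,
    tc: TimecourseMatrix,
    design_norm: bool = True,
    demean: bool = True,
) -> tuple[SubjectMapSet, ResidualSummary]:
    """Temporal regression of the stage-1 timecourses into the same data.

    Returns the N x M subject-specific spatial maps (raw B_sm if
    ``design_norm`` is false, semi-standardized B_sm* if true) together
    with the voxelwise residual standard deviations of the fit.
    """
    if y.n_timepoints != tc.n_timepoints:
        raise ValueError(
            f"timepoint mismatch: data has {y.n_timepoints}, timecourses have {tc.n_timepoints}"
        )
    if y.n_timepoints < tc.n_components + 2:
        raise ValueError("too few timepoints for the number of components")
    if design_norm:
        tc = normalize_design(tc)
    design = tc.data.T.copy()  # T x M
    data = y.data
    if demean:
        design -= design.mean(axis=0, keepdims=True)
        data = data - data.mean(axis=1, keepdims=True)
    pinv = _check_rank(design, tc.component_names, "stage 2")
    b_sm = (pinv @ data.T).T  # N x M
    resid = data.T - design @ b_sm.T  # T x N
    dof = max(design.shape[0] - design.shape[1] - (1 if demean else 0), 1)
    resid_std = np.sqrt((resid**2).sum(axis=0) / dof)
    maps = SubjectMapSet(
        data=b_sm,
        grid=y.grid,
        design_normalized=design_norm,
        subject_id=y.subject_id,
        mask=y.mask,
        component_names=tc.component_names,
    )
    return maps, ResidualSummary(stage2_resid_std=resid_std)


@dataclass
class DualRegressionResults:
    """Fitted dual-regression quantities for one subject.

    Attributes
    ----------
    timecourses : TimecourseMatrix
        Stage-1 network timecourses (pre-normalization), with amplitudes.
    maps : SubjectMapSet
        Stage-2 subject-specific spatial maps (B_sm* when design-normalized).
    residuals : ResidualSummary
        Stage-2 voxelwise residual standard deviations.
    """

    timecourses: TimecourseMatrix
    maps: SubjectMapSet
    residuals: ResidualSummary
    design_norm: bool
    demean: bool

    @property
    def amplitudes(self) -> np.ndarray:
        """Network amplitudes a_i (std of each stage-1 timecourse)."""
        return self.timecourses.amplitudes

    def summary(self) -> str:
        names = self.timecourses.component_names or [
            f"IC{i}" for i in range(self.timecourses.n_components)
        ]
        kind = "B_sm* (design-normalized)" if self.design_norm else "B_sm (raw coefficients)"
        lines = [
            "Dual regression results"
            + (f" — subject {self.maps.subject_id}" if self.maps.subject_id else ""),
            f"  components: {self.timecourses.n_components}, "
            f"timepoints: {self.timecourses.n_timepoints}, voxels: {self.maps.n_voxels}",
            f"  stage-2 statistic: {kind}",
            f"  {'component':<12} {'amplitude':>10} {'|map| max':>10}",
        ]
        for i, name in enumerate(names):
            lines.append(
                f"  {name:<12} {self.amplitudes[i]:>10.4f} "
                f"{np.abs(self.maps.data[:, i]).max():>10.4f}"
            )
        med = float(np.median(self.residuals.stage2_resid_std))
        lines.append(f"  median stage-2 residual std: {med:.4f}")
        return "\n".join(lines)


class DualRegression:
    """Dual-regression model for one subject against a template map set.

    Parameters
    ----------
    data : BOLDDataset
        The subject's BOLD data, N voxels x T timepoints.
    templates : SpatialMapSet
        Unthresholded template network maps shared across subjects.
    demean : bool
        Mean-center data and regressors in both stages (default True).

    ``fit(design_norm=True)`` runs both stages and returns a
    :class:`DualRegressionResults`.
    """

    def __init__(self, data: BOLDDataset, templates: SpatialMapSet, demean: bool = True):
        if data.n_voxels != templates.n_voxels:
            raise ValueError("data and templates disagree on voxel count")
        self.data = data
        self.templates = templates
        self.demean = demean

    def fit(self, design_norm: bool = True) -> DualRegressionResults:
        if not design_norm:
            logger.warning(
                "design normalization disabled: raw stage-2 coefficient maps are "
                "insensitive to network-wide amplitude and mislocalize within-network "
                "amplitude effects; they should not be used for group-level inference"
            )
        tc = stage1(self.data, self.templates, demean=self.demean)
        maps, resid = stage2(self.data, tc, design_norm=design_norm, demean=self.demean)
        return DualRegressionResults(
            timecourses=tc, maps=maps, residuals=resid,
            design_norm=design_norm, demean=self.demean,
        )


def run_dual_regression(
    subjects,
    s: SpatialMapSet,
    design_norm: bool = True,
    outdir=None,
    demean: bool = True,
    mask_path=None,
    tr: float | None = None,
) -> list[DualRegressionResults]:
    """Run dual regression over a cohort and emit FSL-dialect outputs.

    ``subjects`` is an ordered list of BOLD image paths or
    :class:`~dualreg.core.BOLDDataset` objects.  For each subject ``i``
    (0-based, following input order) ``dr_stage1_subject{i:05d}.txt`` and
    ``dr_stage2_subject{i:05d}.nii.gz`` are written under ``outdir``,
    along with a JSON manifest recording options and software version.
    Aborts on the first structural mismatch, naming the subject.
    """
    results: list[DualRegressionResults] = []
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    subject_ids = []
    for i, subj in enumerate(subjects):
        if isinstance(subj, BOLDDataset):
            ds = subj
        else:
            ds = read_bold(subj, mask=mask_path, tr=tr, subject_id=str(subj))
        if not ds.subject_id:
            ds.subject_id = f"subject{i:05d}"
        try:
            res = DualRegression(ds, s, demean=demean).fit(design_norm=design_norm)
        except ValueError as exc:
            raise ValueError(f"subject {ds.subject_id} (index {i}): {exc}") from exc
        results.append(res)
        subject_ids.append(ds.subject_id)
        if outdir is not None:
            write_stage1_text(res.timecourses, outdir / stage1_filename(i))
            write_4d_image(res.maps, outdir / stage2_filename(i))
    if outdir is not None:
        manifest = {
            "tool": "dualreg",
            "version": __version__,
            "design_norm": bool(design_norm),
            "demean": bool(demean),
            "mask": str(mask_path) if mask_path is not None else None,
            "n_subjects": len(subject_ids),
            "subjects": subject_ids,
            "components": list(s.component_names or []),
        }
        (outdir / "dr_manifest.json").write_text(json.dumps(manifest, indent=2))
    return results
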