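"""Stage-1 timecourse quality control.

Motion that survives preprocessing shows up in stage-1 network timecourses
as spikes and amplitude inflation, and such amplitude effects propagate
into design-normalized group maps where they masquerade as connectivity
differences.  These helpers summarize per-subject network amplitudes,
flag spike-like excursions with a robust z-score (median/MAD, which spikes
cannot inflate the way they inflate an ordinary standard deviation), and
correlate timecourses against external references such as motion
parameter traces.  No automatic subject exclusion is performed: the tables
are inputs to a user's QC policy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import TimecourseMatrix
from .io import read_stage1_text
from .regression import compute_amplitudes

__all__ = ["amplitude_summary", "correlate_with_reference", "spike_metric", "SpikeReport"]

MAD_SCALE = 1.4826  # consistency factor: MAD * 1.4826 estimates sigma for a Gaussian


def amplitude_summary(stage1_dir, groups: dict[str, str] | pd.Series | None = None) -> pd.DataFrame:
    """Per-subject, per-component stage-1 timecourse amplitudes.

    Reads every ``dr_stage1_subject*.txt`` under ``stage1_dir`` and
    returns one row per (subject, component) with the timecourse standard
    deviation and an optional group label (``groups`` maps subject stem ->
    label).  Malformed files are reported individually.
    """
    stage1_dir = Path(stage1_dir)
    files = sorted(stage1_dir.glob("dr_stage1_subject*.txt"))
    if not files:
        raise FileNotFoundError(f"no dr_stage1_subject*.txt files in {stage1_dir}")
    rows, errors = [], []
    for f in files:
        subject = f.stem.replace("dr_stage1_", "")
        try:
            tc = read_stage1_text(f, subject_id=subject)
        except ValueError as exc:
            errors.append(str(exc))
            continue
        amps = compute_amplitudes(tc)
        group = None
        if groups is not None:
            group = groups.get(subject) if hasattr(groups, "get") else groups[subject]
        for c, a in enumerate(amps):
            rows.append({"subject": subject, "component": c, "amplitude": float(a), "group": group})
    if errors:
        raise ValueError("malformed stage-1 files:\n  " + "\n  ".join(errors))
    return pd.DataFrame(rows, columns=["subject", "component", "amplitude", "group"])


def group_amplitude_quartiles(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group, per-component amplitude quartiles of an amplitude table."""
    return (
        table.groupby(["group", "component"])["amplitude"]
        .quantile([0.25, 0.5, 0.75])
        .unstack()
        .rename(columns={0.25: "q1", 0.5: "median", 0.75: "q3"})
        .reset_index()
    )


def correlate_with_reference(
    tc: TimecourseMatrix, reference: np.ndarray, component: int, demean: bool = True
) -> float:
    """Pearson correlation between one network timecourse and a reference.

    Typical use: compare a suspicious stage-1 timecourse with a motion
    parameter trace to confirm a motion origin.
    """
    x = np.asarray(tc.data[component], dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: timecourse {x.shape[0]}, reference {y.shape[0]}")
    if demean:
        x = x - x.mean()
        y = y - y.mean()
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance input to correlation")
    return float(np.clip((x @ y) / (x.size * sx * sy), -1.0, 1.0))


@dataclass
class SpikeReport:
    """Spike flags per (subject, component)."""

    table: pd.DataFrame  # columns: component, n_spikes, max_abs_z, timepoints
    cutoff: float


def spike_metric(tc: TimecourseMatrix, cutoff: float = 5.0) -> SpikeReport:
    """Flag spike-like samples by robust z-score.

    For each component, z = (x - median) / (1.4826 * MAD); samples with
    |z| > cutoff are flagged.  A zero MAD (degenerate series) is an error.
    Flags are invariant to affine rescaling of the whole timecourse.
    """
    if tc.n_timepoints < 10:
        raise ValueError("need at least 10 timepoints for spike detection")
    rows = []
    for c in range(tc.n_components):
        x = tc.data[c]
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        if mad == 0:
            name = tc.component_names[c] if tc.component_names else str(c)
            raise ValueError(f"component {name}: MAD is zero (degenerate series)")
        z = (x - med) / (MAD_SCALE * mad)
        hits = np.flatnonzero(np.abs(z) > cutoff)
        rows.append({
            "component": c,
            "n_spikes": int(hits.size),
            "max_abs_z": float(np.abs(z).max()),
            "timepoints": hits.tolist(),
        })
    table = pd.DataFrame(rows, columns=["component", "n_spikes", "max_abs_z", "timepoints"])
    table.insert(0, "subject", tc.subject_id)
    return SpikeReport(table=table, cutoff=cutoff)
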