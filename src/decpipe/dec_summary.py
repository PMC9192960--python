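"""Per-subject DEC summaries and motion quality control.

Each subject's DEC trajectory is reduced to the two dependent variables
used for inference — the per-connection mean (direction/magnitude of
the influence) and sample standard deviation (its variability).  Motion
QC flags subjects whose DVARS (spatial SD of successive difference
images) exceeds the cohort mean by more than two cohort SDs, computed
once per dataset with a strict inequality.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dmvar import DecTrajectory

__all__ = ["summarize_dec", "compute_dvars", "flag_high_motion", "attach_summaries"]


def summarize_dec(traj: DecTrajectory) -> pd.DataFrame:
    """Arithmetic mean and sample SD (ddof=1) of each connection's DEC.

    Returns a frame with columns ``connection``, ``mean``, ``sd``.
    Refuses trajectories with fewer than two retained time points (the
    sample SD would be undefined).
    """
    if traj.values.shape[0] < 2:
        raise ValueError("need at least two time points to compute mean and SD")
    return pd.DataFrame(
        {
            "connection": traj.labels,
            "mean": traj.values.mean(axis=0),
            "sd": traj.values.std(axis=0, ddof=1),
        }
    )


def compute_dvars(data) -> tuple[np.ndarray, float]:
    """DVARS: spatial SD of each successive difference image.

    ``data`` is either a 4-D array (x, y, z, t) or a 2-D (time x voxel/
    region) matrix.  Returns the per-transition values (length T-1) and
    the subject scalar (their mean).
    """
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 4:
        arr = arr.reshape(-1, arr.shape[3]).T  # -> time x voxel
    if arr.ndim != 2:
        raise ValueError("expected a 4-D image or a time x voxel matrix")
    if arr.shape[0] < 2:
        raise ValueError("need at least two volumes to compute DVARS")
    diffs = np.diff(arr, axis=0)
    per_volume = diffs.std(axis=1, ddof=1) if arr.shape[1] > 1 else np.zeros(arr.shape[0] - 1)
    return per_volume, float(per_volume.mean())


def flag_high_motion(dvars) -> np.ndarray:
    """Boolean exclusion flags: DVARS strictly above cohort mean + 2 SD.

    The threshold is computed once from all subjects of the dataset (no
    iterative recomputation); a zero-variance cohort flags nobody.
    """
    x = np.asarray(dvars, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need a 1-D vector of at least 3 subjects")
    if not np.isfinite(x).all():
        raise ValueError("DVARS values must be finite")
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros(len(x), dtype=bool)
    return x > x.mean() + 2.0 * sd


def attach_summaries(table: pd.DataFrame, summaries: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Merge per-subject DEC summaries into a cohort table.

    ``summaries`` maps subject_id to the frame from :func:`summarize_dec`.
    Adds ``mean__<connection>`` and ``sd__<connection>`` columns and an
    ``excluded`` flag from the motion QC rule.
    """
    out = table.copy()
    for sid, summ in summaries.items():
        for _, row in summ.iterrows():
            out.loc[out.subject_id == sid, f"mean__{row.connection}"] = row["mean"]
            out.loc[out.subject_id == sid, f"sd__{row.connection}"] = row["sd"]
    out["excluded"] = flag_high_motion(out["dvars"].to_numpy())
    return out
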