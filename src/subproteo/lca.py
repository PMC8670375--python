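"""Live-cell-array analysis: background subtraction and promoter activity.

Promoter activity is reported in arbitrary transcriptional activity units
(TAU): after subtracting the background fluorescence of reporter-free
control strains (averaged over control wells per time point), the activity
at time t is the GFP increment over the previous reading divided by the
culture density,

    TAU_t = (GFP_t - GFP_{t-1}) / OD600_t .

TAU is undefined at the first time point and negative values (bleaching,
noise) are kept as-is.  The telescoping difference makes TAU exactly
invariant under any time-constant fluorescence offset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def subtract_background(series: pd.DataFrame) -> pd.DataFrame:
    """Subtract the mean control-well GFP from every reporter well, per time
    point.  Requires at least one control well on the same time grid."""
    controls = series[series["role"] == "control"]
    reporters = series[series["role"] == "reporter"].copy()
    if controls.empty:
        raise ValueError("no control wells for background subtraction")
    background = controls.groupby("time_min")["gfp"].mean()
    reporter_times = set(reporters["time_min"].unique())
    if not reporter_times.issubset(set(background.index)):
        raise ValueError("control and reporter wells are on different time grids")
    reporters["gfp"] = reporters["gfp"] - reporters["time_min"].map(background)
    return reporters


def compute_tau(corrected: pd.DataFrame) -> pd.DataFrame:
    """TAU per reporter well and time point (first point absent).

    Points where OD600 is non-positive are flagged (``od_invalid``) and get
    NaN TAU rather than aborting the whole series.
    """
    out = []
    for well, grp in corrected.sort_values("time_min").groupby("well"):
        gfp = grp["gfp"].to_numpy(dtype=float)
        od = grp["od600"].to_numpy(dtype=float)
        t = grp["time_min"].to_numpy(dtype=float)
        if len(t) < 2:
            raise ValueError(f"well {well}: need at least 2 time points")
        dgfp = np.diff(gfp)
        od_t = od[1:]
        invalid = od_t <= 0
        with np.errstate(divide="ignore", invalid="ignore"):
            tau = np.where(invalid, np.nan, dgfp / od_t)
        out.append(
            pd.DataFrame(
                {
                    "well": well,
                    "strain": grp["strain"].iloc[0],
                    "time_min": t[1:],
                    "tau": tau,
                    "od_invalid": invalid,
                    "gfp": gfp[1:],
                    "od600": od_t,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def summarize_tau(tau_series: pd.DataFrame):
    """Per-strain TAU profile (mean +/- SD over replicate wells), the
    area under the mean profile, and the strain ranking by that area.

    Returns ``(profile, auc, ranking)``; ranking is ascending in AUC.
    """
    profile = (
        tau_series.groupby(["strain", "time_min"])["tau"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=0) if len(x) > 1 else 0.0)
        .reset_index()
    )
    auc = {}
    for strain, grp in profile.groupby("strain"):
        grp = grp.dropna(subset=["mean"]).sort_values("time_min")
        auc[strain] = float(
            np.trapezoid(grp["mean"].to_numpy(), grp["time_min"].to_numpy())
        )
    ranking = sorted(auc, key=auc.get)
    return profile, auc, ranking
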