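"""Generation-time estimation from OD curves and the toxicity contrast.

The doubling time is the reciprocal of the steepest log2-linear slope over
sliding windows of the blank-subtracted curve; toxicity is tested as the
replicate-wise excess generation time of the fusion construct over the
expression control, compared between mutant and wild type with Student's t.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from inclusion_screen.screen_stats import students_t

_OD_FLOOR = 1e-4


@dataclass
class GrowthCurve:
    """One well's OD time series on a uniform grid."""

    times: np.ndarray
    od: np.ndarray
    strain_id: str = ""
    construct: str = "dsRed_SY1"
    replicate: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape or self.times.ndim != 1:
            raise ValueError("times and od must be matching 1-D arrays")
        steps = np.diff(self.times)
        if len(steps) and (np.any(steps <= 0) or np.ptp(steps) > 1e-9):
            raise ValueError("times must be strictly increasing and uniform")
        if np.any(self.od < 0):
            raise ValueError("od values must be >= 0")


@dataclass
class GenerationTime:
    """Doubling time from the best-fit exponential window."""

    g_hours: float
    window: tuple[int, int]  # (start index, end index) inclusive
    fit_r2: float
    blank_od: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.g_hours) and self.g_hours > 0):
            raise ValueError("g_hours must be finite and positive")


@dataclass
class ToxicityResult:
    """Excess doubling-time contrast for one mutant versus wild type."""

    strain_id: str
    delta_g: np.ndarray          # per-replicate g(fusion) - g(control), hours
    wt_delta_g: np.ndarray
    delta_delta_g: float
    t_stat: float
    p_value: float
    significant: bool


def generation_time(
    curve: GrowthCurve,
    blank: float | str = 0.0,
    window_points: int = 9,
    min_od: float = 0.1,
    smooth: int = 5,
) -> GenerationTime:
    """Doubling time from the steepest sliding-window log2-linear fit.

    ``blank`` is subtracted before the log (pass ``"auto"`` to use the
    median of the first 3 readings — appropriate only when the pre-growth
    baseline is pure blank); ``min_od`` restricts candidate windows to
    blank-subtracted ODs at or above it, keeping the fit out of the noisy
    near-baseline region; ``smooth`` applies a centered moving average to
    the log-OD trace (exactly slope-preserving on log-linear segments).
    Raises when no window shows positive growth.
    """
    n = len(curve.od)
    if window_points < 2 or n < window_points:
        raise ValueError("need at least window_points samples")
    if blank == "auto":
        blank_val = float(np.median(curve.od[:3]))
    else:
        blank_val = float(blank)
    if blank_val >= float(curve.od.max()):
        raise ValueError("blank exceeds the curve maximum")
    od = np.clip(curve.od - blank_val, _OD_FLOOR, None)
    y = np.log2(od)
    if smooth > 1:
        y = uniform_filter1d(y, size=smooth, mode="nearest")
    t = curve.times

    windows_y = np.lib.stride_tricks.sliding_window_view(y, window_points)
    windows_t = np.lib.stride_tricks.sliding_window_view(t, window_points)
    tc = windows_t - windows_t.mean(axis=1, keepdims=True)
    yc = windows_y - windows_y.mean(axis=1, keepdims=True)
    var_t = (tc**2).sum(axis=1)
    slopes = (tc * yc).sum(axis=1) / var_t

    windows_od = np.lib.stride_tricks.sliding_window_view(od, window_points)
    eligible = windows_od.min(axis=1) >= min_od
    if not eligible.any():
        eligible = np.ones(len(slopes), dtype=bool)  # fall back to all windows
    candidate = np.where(eligible, slopes, -np.inf)
    best = int(np.argmax(candidate))
    slope = slopes[best]
    if slope <= 0:
        raise ValueError("no window with positive growth")

    ss_tot = (yc[best] ** 2).sum()
    ss_res = ss_tot - slope**2 * var_t[best]
    r2 = 1.0 if ss_tot == 0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return GenerationTime(
        g_hours=float(1.0 / slope),
        window=(best, best + window_points - 1),
        fit_r2=float(r2),
        blank_od=blank_val,
    )


def _paired_deltas(curves: list[GrowthCurve], **gt_kwargs) -> np.ndarray:
    """Replicate-wise g(dsRed_SY1) - g(dsRed_only) for one strain."""
    by_construct: dict[str, dict[int, GrowthCurve]] = {}
    for curve in curves:
        by_construct.setdefault(curve.construct, {})[curve.replicate] = curve
    for construct in ("dsRed_SY1", "dsRed_only"):
        if construct not in by_construct:
            raise ValueError(f"missing construct {construct}")
    fusion = by_construct["dsRed_SY1"]
    control = by_construct["dsRed_only"]
    shared = sorted(set(fusion) & set(control))
    if len(shared) < 3:
        raise ValueError("need >= 3 paired replicates per construct")
    return np.array(
        [
            generation_time(fusion[r], **gt_kwargs).g_hours
            - generation_time(control[r], **gt_kwargs).g_hours
            for r in shared
        ]
    )


def toxicity_test(
    mutant_curves: list[GrowthCurve],
    wt_curves: list[GrowthCurve],
    alpha: float = 0.05,
    **gt_kwargs,
) -> ToxicityResult:
    """Test whether the fusion construct slows the mutant more than WT.

    For each strain, per-replicate delta_g = g(fusion) - g(control); the
    mutant and wild-type delta_g samples are compared with the two-sample
    Student's t-test.
    """
    mut_delta = _paired_deltas(mutant_curves, **gt_kwargs)
    wt_delta = _paired_deltas(wt_curves, **gt_kwargs)
    t_stat, p = students_t(mut_delta, wt_delta)
    strain_ids = {c.strain_id for c in mutant_curves}
    return ToxicityResult(
        strain_id=strain_ids.pop() if len(strain_ids) == 1 else "mixed",
        delta_g=mut_delta,
        wt_delta_g=wt_delta,
        delta_delta_g=float(mut_delta.mean() - wt_delta.mean()),
        t_stat=t_stat,
        p_value=p,
        significant=p <= alpha,
    )


# ---------------------------------------------------------------------------
# I/O


def read_growth_csv(
    od_path: str | Path, platemap_path: str | Path
) -> list[GrowthCurve]:
    """Wide-format OD CSV (time_h + one column per well) with a well map.

    The plate map needs columns well, strain_id, construct and optionally
    replicate (defaults to order of appearance).
    """
    table = pd.read_csv(od_path)
    if "time_h" not in table.columns:
        raise ValueError("growth CSV needs a time_h column")
    pm = pd.read_csv(platemap_path)
    missing = {"well", "strain_id", "construct"} - set(pm.columns)
    if missing:
        raise ValueError(f"growth plate map missing columns {sorted(missing)}")
    times = table["time_h"].to_numpy()
    curves = []
    counters: dict[tuple[str, str], int] = {}
    for row in pm.itertuples(index=False):
        well = str(row.well)
        if well not in table.columns:
            raise ValueError(f"well {well} not present in growth CSV")
        key = (str(row.strain_id), str(row.construct))
        rep = int(getattr(row, "replicate", counters.get(key, 0)))
        counters[key] = rep + 1
        curves.append(
            GrowthCurve(
                times=times,
                od=table[well].to_numpy(),
                strain_id=str(row.strain_id),
                construct=str(row.construct),
                replicate=rep,
            )
        )
    return curves


def generation_times_frame(curves: list[GrowthCurve], **gt_kwargs) -> pd.DataFrame:
    rows = []
    for curve in curves:
        gt = generation_time(curve, **gt_kwargs)
        rows.append(
            {
                "strain_id": curve.strain_id,
                "construct": curve.construct,
                "replicate": curve.replicate,
                "g_hours": gt.g_hours,
                "fit_r2": gt.fit_r2,
                "window_start": gt.window[0],
                "window_end": gt.window[1],
                "blank_od": gt.blank_od,
            }
        )
    return pd.DataFrame(rows)


def toxicity_frame(
    curves: list[GrowthCurve], wt_strain: str, alpha: float = 0.05, **gt_kwargs
) -> pd.DataFrame:
    """Per-mutant toxicity table against one wild-type reference strain."""
    by_strain: dict[str, list[GrowthCurve]] = {}
    for curve in curves:
        by_strain.setdefault(curve.strain_id, []).append(curve)
    if wt_strain not in by_strain:
        raise ValueError(f"wild-type strain {wt_strain!r} absent from curves")
    rows = []
    for strain, strain_curves in sorted(by_strain.items()):
        if strain == wt_strain:
            continue
        res = toxicity_test(strain_curves, by_strain[wt_strain], alpha=alpha, **gt_kwargs)
        rows.append(
            {
                "strain_id": strain,
                "delta_g_mean": res.delta_g.mean(),
                "delta_g_sd": res.delta_g.std(ddof=1),
                "delta_delta_g": res.delta_delta_g,
                "t_stat": res.t_stat,
                "p_value": res.p_value,
                "significant": res.significant,
            }
        )
    return pd.DataFrame(rows)
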