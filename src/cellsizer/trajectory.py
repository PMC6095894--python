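"""Processing of single-cell volume time series.

Implements the fixed processing order despike -> smooth -> growth speed /
event annotation, plus G1/S detection from a cell-cycle reporter channel and
pooled growth-speed-versus-volume analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from cellsizer.homeostasis import weighted_binned_fit

__all__ = [
    "Trajectory",
    "GrowthSpeedSeries",
    "CycleEvents",
    "remove_spike_outliers",
    "smooth",
    "instantaneous_growth_speed",
    "annotate_events",
    "detect_g1s",
    "growth_speed_vs_volume_bins",
    "percentile_groups",
]

#: conversion from per-minute to per-hour slopes
_MIN_PER_H = 60.0

#: event offsets relative to cytokinesis onset, in minutes
BIRTH_OFFSET_MIN = 40.0
MITOSIS_OFFSET_MIN = 60.0


@dataclass
class Trajectory:
    """A sampled single-cell volume time series.

    Attributes
    ----------
    cell_id:
        Identifier of the tracked cell (or lineage segment).
    t:
        Sample times in minutes, strictly increasing.
    volume:
        Volume in µm³ at each retained sample.
    reporter:
        Cell-cycle reporter fluorescence (arbitrary units), or ``None``.
    frame_interval:
        Nominal sampling interval in minutes (constant per trajectory).
    frames:
        Original frame indices of the retained samples. Frames dropped by
        despiking disappear from all arrays but keep their index here.
    cytokinesis_onsets:
        Times (min) of cytokinesis onsets bracketing the recorded cycle(s).
    ground_truth:
        Optional dictionary of simulation ground truth (events, spikes...).
    """

    cell_id: str
    t: np.ndarray
    volume: np.ndarray
    reporter: np.ndarray | None = None
    frame_interval: float = 10.0
    frames: np.ndarray | None = None
    cytokinesis_onsets: list[float] = field(default_factory=list)
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        if self.reporter is not None:
            self.reporter = np.asarray(self.reporter, dtype=float)
        if self.frames is None:
            self.frames = np.arange(self.t.size)
        else:
            self.frames = np.asarray(self.frames, dtype=int)
        if self.t.size != self.volume.size:
            raise ValueError("t and volume must have the same length")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("sample times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.t.size)

    def take(self, keep: np.ndarray) -> "Trajectory":
        """Return a copy restricted to the boolean mask ``keep``."""
        rep = self.reporter[keep] if self.reporter is not None else None
        return replace(
            self,
            t=self.t[keep],
            volume=self.volume[keep],
            reporter=rep,
            frames=self.frames[keep],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "frame": self.frames,
                "t_min": self.t,
                "volume_um3": self.volume,
            }
        )
        df["reporter"] = self.reporter if self.reporter is not None else np.nan
        return df


@dataclass
class GrowthSpeedSeries:
    """Per-frame instantaneous growth speed dV/dt in µm³/h."""

    cell_id: str
    t: np.ndarray
    volume: np.ndarray
    dvdt: np.ndarray
    valid: np.ndarray
    window_halfwidth: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "t_min": self.t,
                "volume_um3": self.volume,
                "dvdt_um3_per_h": self.dvdt,
                "valid": self.valid,
            }
        )


@dataclass
class CycleEvents:
    """Key cell-cycle sample points of one recorded cycle (times in min)."""

    cell_id: str
    t_birth: float = np.nan
    V_birth: float = np.nan
    t_G1S: float = np.nan
    V_G1S: float = np.nan
    t_mitosis: float = np.nan
    V_mitosis: float = np.nan


def remove_spike_outliers(
    traj: Trajectory,
    window: int = 11,
    k: float = 3.0,
    atol: float = 1e-9,
) -> tuple[Trajectory, int]:
    """Drop isolated segmentation spikes from a volume series.

    A frame is dropped iff its volume deviates from the median of the local
    window by more than ``k * 1.4826 * MAD``. Dropped frames are removed, not
    interpolated; their indices stay visible through ``frames``. When the
    local MAD is zero (all-identical window) only points farther than
    ``atol`` from the median are dropped.

    Returns the despiked trajectory and the number of frames removed.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    v = traj.volume
    n = v.size
    if n == 0:
        return traj, 0
    half = window // 2
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        local = v[lo:hi]
        med = np.median(local)
        mad = np.median(np.abs(local - med))
        thresh = k * 1.4826 * mad if mad > 0 else atol
        if abs(v[i] - med) > thresh:
            keep[i] = False
    return traj.take(keep), int((~keep).sum())


def smooth(traj: Trajectory, window: int = 7) -> Trajectory:
    """Centered sliding-average smoothing; edges use the shrunken window."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    sm = (
        pd.Series(traj.volume)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return replace(traj, volume=sm)


def _theil_sen_slope(t: np.ndarray, v: np.ndarray) -> float:
    """Median of all pairwise slopes (deterministic Theil-Sen)."""
    n = t.size
    idx_i, idx_j = np.triu_indices(n, k=1)
    dt = t[idx_j] - t[idx_i]
    return float(np.median((v[idx_j] - v[idx_i]) / dt))


def instantaneous_growth_speed(traj: Trajectory, window: int = 9) -> GrowthSpeedSeries:
    """Per-frame growth speed from a robust linear fit on a centered window.

    The slope at each frame is the Theil-Sen estimate (median of pairwise
    slopes) over the ``window`` frames centered there, converted to µm³/h.
    Frames whose centered window holds fewer than 5 valid samples are marked
    invalid. Input should already be despiked and smoothed.
    """
    if window < 5 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 5")
    t, v = traj.t, traj.volume
    n = t.size
    half = window // 2
    dvdt = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for i in range(n):
        lo, hi = i - half, i + half + 1
        if lo < 0 or hi > n:
            continue  # incomplete window at trajectory edge
        tw, vw = t[lo:hi], v[lo:hi]
        ok = np.isfinite(vw)
        if ok.sum() < 5:
            continue
        dvdt[i] = _theil_sen_slope(tw[ok], vw[ok]) * _MIN_PER_H
        valid[i] = True
    return GrowthSpeedSeries(
        cell_id=traj.cell_id,
        t=t,
        volume=v,
        dvdt=dvdt,
        valid=valid,
        window_halfwidth=half,
    )


def _snap(traj: Trajectory, target: float) -> int | None:
    """Index of the sampled frame nearest ``target`` (ties round down)."""
    if traj.t.size == 0:
        return None
    if target < traj.t[0] or target > traj.t[-1]:
        return None
    d = np.abs(traj.t - target)
    return int(np.argmin(d))  # argmin returns the first (earlier) minimum


def annotate_events(traj: Trajectory, detect_g1s_events: bool = True) -> list[CycleEvents]:
    """Read cell-cycle event volumes outside the mitotic overshoot window.

    Birth is sampled 40 min after a cytokinesis onset and mitotic entry
    60 min before the next onset; both are snapped to the nearest recorded
    frame. Events falling outside the recorded range are left missing, never
    extrapolated. Volumes are read from the (ideally smoothed) series.
    """
    if not traj.cytokinesis_onsets:
        raise ValueError("trajectory has no cytokinesis onsets")
    onsets = sorted(traj.cytokinesis_onsets)
    events: list[CycleEvents] = []
    for a, b in zip(onsets[:-1], onsets[1:]):
        ev = CycleEvents(cell_id=traj.cell_id)
        i = _snap(traj, a + BIRTH_OFFSET_MIN)
        if i is not None:
            ev.t_birth = float(traj.t[i])
            ev.V_birth = float(traj.volume[i])
        j = _snap(traj, b - MITOSIS_OFFSET_MIN)
        if j is not None:
            ev.t_mitosis = float(traj.t[j])
            ev.V_mitosis = float(traj.volume[j])
        if detect_g1s_events and traj.reporter is not None:
            t_g1s = detect_g1s(traj)
            if np.isfinite(t_g1s) and (
                np.isnan(ev.t_birth) or t_g1s > ev.t_birth
            ):
                g = _snap(traj, t_g1s)
                if g is not None:
                    ev.t_G1S = float(traj.t[g])
                    ev.V_G1S = float(traj.volume[g])
        events.append(ev)
    return events


def detect_g1s(
    traj: Trajectory,
    k: float = 3.0,
    m: int = 3,
    n_background: int = 10,
) -> float:
    """First time the reporter exceeds background for ``m`` consecutive frames.

    Background mean and s.d. are estimated from the first ``n_background``
    frames after birth (cytokinesis onset + 40 min, or the start of the
    series when no onset is recorded). Returns NaN when no crossing is found;
    warns when the crossing starts at the very first usable frame (the
    background estimate is then unreliable).
    """
    if traj.reporter is None:
        raise ValueError("trajectory has no reporter channel")
    t_start = traj.t[0]
    if traj.cytokinesis_onsets:
        t_start = max(t_start, min(traj.cytokinesis_onsets) + BIRTH_OFFSET_MIN)
    sel = traj.t >= t_start
    t, rep = traj.t[sel], traj.reporter[sel]
    if t.size < n_background:
        raise ValueError(
            f"need at least {n_background} frames after birth to estimate background"
        )
    bg_mean = float(np.mean(rep[:n_background]))
    bg_sd = float(np.std(rep[:n_background], ddof=1))
    above = rep > bg_mean + k * bg_sd
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run == m:
            first = i - m + 1
            if first == 0:
                warnings.warn(
                    "reporter already above background at the first frame; "
                    "G1/S call unreliable",
                    stacklevel=2,
                )
            return float(t[first])
    return float("nan")


def growth_speed_vs_volume_bins(
    series: list[GrowthSpeedSeries],
    n_bins: int = 10,
    min_distinct_cells: int = 5,
):
    """Average-bin growth speed against volume, pooled over cells and frames.

    Points from all valid frames of all cells are pooled, binned into
    ``n_bins`` equal-width volume bins, and bins contributed to by fewer
    than ``min_distinct_cells`` distinct cells are dropped. A count-weighted
    linear fit of speed on volume follows; its slope is the population
    growth rate (1/h).

    Returns ``(bins, fit)`` where ``bins`` is a DataFrame and ``fit`` a
    :class:`~cellsizer.homeostasis.BinnedRegressionResult`.
    """
    if len(series) < min_distinct_cells:
        raise ValueError(
            f"need at least {min_distinct_cells} cells, got {len(series)}"
        )
    vol, spd, cid = [], [], []
    for s in series:
        ok = s.valid & np.isfinite(s.dvdt)
        vol.append(s.volume[ok])
        spd.append(s.dvdt[ok])
        cid.extend([s.cell_id] * int(ok.sum()))
    v = np.concatenate(vol)
    y = np.concatenate(spd)
    cells = np.asarray(cid)
    if v.size == 0:
        raise ValueError("no valid growth-speed samples")
    edges = np.linspace(v.min(), v.max(), n_bins + 1)
    idx = np.clip(np.digitize(v, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        if np.unique(cells[sel]).size < min_distinct_cells:
            continue
        rows.append(
            {
                "x_stat": float(np.mean(v[sel])),
                "y_stat": float(np.mean(y[sel])),
                "count": int(sel.sum()),
                "y_sd": float(np.std(y[sel], ddof=1)) if sel.sum() > 1 else 0.0,
            }
        )
    if len(rows) < 2:
        raise ValueError(
            "fewer than 2 volume bins retain >= "
            f"{min_distinct_cells} distinct cells; cannot fit"
        )
    bins = pd.DataFrame(rows)
    fit = weighted_binned_fit(bins, n_cells=len(series))
    return bins, fit


def percentile_groups(
    table: pd.DataFrame,
    column: str,
    cuts: tuple[float, float] = (20.0, 80.0),
) -> pd.Series:
    """Label rows 'low'/'mid'/'high' by empirical percentiles of ``column``.

    Groups are [0, cuts[0]), [cuts[0], cuts[1]), [cuts[1], 100]; values tied
    exactly with the lower cut go to the lower group. Degenerate input (all
    values identical) puts everything in 'mid' with a warning.
    """
    if len(table) < 10:
        raise ValueError("need at least 10 cells to form percentile groups")
    x = table[column].to_numpy(dtype=float)
    lo_cut, hi_cut = np.percentile(x, cuts)
    if lo_cut == hi_cut:
        warnings.warn(
            f"degenerate percentile cuts for column {column!r}; "
            "all cells assigned to the middle group",
            stacklevel=2,
        )
        return pd.Series("mid", index=table.index, name=f"{column}_group")
    labels = np.where(x <= lo_cut, "low", np.where(x > hi_cut, "high", "mid"))
    return pd.Series(labels, index=table.index, name=f"{column}_group")
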