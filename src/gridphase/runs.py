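"""Segmentation of trajectories into single firing-field traversals ("runs").

A run is one maximal contiguous passage of the path through one field
mask; entry and exit points are linearly interpolated onto the mask
boundary so path lengths are continuous rather than bin-quantized.  Each
run carries the four path properties used throughout the analysis:

1. path length, measured along the trajectory from field entry to exit;
2. tortuosity, path length / straight entry-exit distance (>= 1);
3. eccentricity, shortest distance between path and firing-field peak;
4. average speed within the field (path length / duration).

Filters: the primary spike-count criterion keeps runs with *more than*
``min_spikes`` spikes (strict); an optional robustness filter additionally
requires at least 3 theta cycles and an instantaneous speed never below
1 cm/s.  Runs with tortuosity < 1.4 are tagged "straight".
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .ratemap import FiringField, RateMap
from .synthetic import Trajectory

__all__ = [
    "RunRecord",
    "segment_runs",
    "path_metrics",
    "attach_spikes",
    "filter_runs",
    "split_halves",
]

_SUBDIV = 32  # sub-sampling of the entry/exit segment for boundary interpolation


@dataclass
class RunRecord:
    """One traversal of one firing field."""

    field_id: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    cumdist: np.ndarray = None
    entry_t: float = np.nan
    exit_t: float = np.nan
    path_length: float = np.nan
    tortuosity: float = np.nan
    eccentricity: float = np.nan
    mean_speed: float = np.nan
    min_instant_speed: float = np.nan
    entry_direction_deg: float = np.nan
    spike_t: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    spike_phase_deg: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    spike_dist_cm: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    n_theta_cycles: float = np.nan
    straight: bool = False
    touches_boundary: bool = False

    @property
    def n_spikes(self) -> int:
        return int(self.spike_t.size)

    @property
    def duration(self) -> float:
        return float(self.exit_t - self.entry_t)


def _in_mask(rm: RateMap, mask: np.ndarray, x, y):
    ix = np.floor((np.asarray(x) - rm.x_edges[0]) / rm.bin_size).astype(int)
    iy = np.floor((np.asarray(y) - rm.y_edges[0]) / rm.bin_size).astype(int)
    ny, nx = mask.shape
    inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    out = np.zeros(np.shape(ix), dtype=bool)
    out[inside] = mask[iy[inside], ix[inside]]
    return out


def _boundary_point(rm, mask, t0, x0, y0, t1, x1, y1, entering: bool):
    """Interpolated crossing point of the segment with the mask boundary."""
    frac = np.linspace(0.0, 1.0, _SUBDIV + 1)
    xs = x0 + frac * (x1 - x0)
    ys = y0 + frac * (y1 - y0)
    inm = _in_mask(rm, mask, xs, ys)
    idx = np.flatnonzero(inm) if entering else np.flatnonzero(~inm)
    f = frac[idx[0]] if idx.size else 1.0
    return t0 + f * (t1 - t0), x0 + f * (x1 - x0), y0 + f * (y1 - y0)


def segment_runs(traj: Trajectory, fld: FiringField, rm: RateMap) -> list[RunRecord]:
    """All maximal contiguous traversals of the trajectory through one field."""
    inm = _in_mask(rm, fld.mask, traj.x, traj.y)
    if not inm.any():
        return []
    d = np.diff(inm.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1  # first outside sample
    if inm[0]:
        starts = np.concatenate([[0], starts])
    if inm[-1]:
        ends = np.concatenate([ends, [traj.t.size]])

    runs = []
    for s, e in zip(starts, ends):
        ts = list(traj.t[s:e])
        xs = list(traj.x[s:e])
        ys = list(traj.y[s:e])
        if s > 0:  # interpolate entry onto the boundary
            t0, x0, y0 = _boundary_point(
                rm, fld.mask, traj.t[s - 1], traj.x[s - 1], traj.y[s - 1],
                traj.t[s], traj.x[s], traj.y[s], entering=True,
            )
            if t0 < ts[0]:
                ts, xs, ys = [t0] + ts, [x0] + xs, [y0] + ys
        if e < traj.t.size:  # interpolate exit
            t1, x1, y1 = _boundary_point(
                rm, fld.mask, traj.t[e - 1], traj.x[e - 1], traj.y[e - 1],
                traj.t[e], traj.x[e], traj.y[e], entering=False,
            )
            if t1 > ts[-1]:
                ts, xs, ys = ts + [t1], xs + [x1], ys + [y1]
        if len(ts) < 2:
            continue
        runs.append(
            RunRecord(
                field_id=fld.field_id,
                t=np.asarray(ts),
                x=np.asarray(xs),
                y=np.asarray(ys),
                touches_boundary=fld.touches_boundary,
            )
        )
    return runs


def _point_segment_dist(px, py, ax, ay, bx, by):
    """Distance from point p to segment ab (vectorized over segments)."""
    dx, dy = bx - ax, by - ay
    L2 = dx * dx + dy * dy
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(L2 > 0, ((px - ax) * dx + (py - ay) * dy) / np.where(L2 > 0, L2, 1), 0.0)
    u = np.clip(u, 0.0, 1.0)
    return np.hypot(px - (ax + u * dx), py - (ay + u * dy))


def path_metrics(run: RunRecord, fld: FiringField) -> RunRecord | None:
    """Complete a run with the four path properties; None if degenerate."""
    if run.t.size < 2:
        return None
    dur = float(run.t[-1] - run.t[0])
    if dur <= 0:
        return None
    seg = np.hypot(np.diff(run.x), np.diff(run.y))
    run.cumdist = np.concatenate([[0.0], np.cumsum(seg)])
    run.path_length = float(run.cumdist[-1])
    chord = float(np.hypot(run.x[-1] - run.x[0], run.y[-1] - run.y[0]))
    run.tortuosity = run.path_length / chord if chord > 1e-9 else np.inf
    px, py = fld.peak_xy
    run.eccentricity = float(
        np.min(_point_segment_dist(px, py, run.x[:-1], run.y[:-1], run.x[1:], run.y[1:]))
    )
    run.entry_t, run.exit_t = float(run.t[0]), float(run.t[-1])
    run.mean_speed = run.path_length / dur
    dt = np.gradient(run.t)
    run.min_instant_speed = float(
        np.min(np.hypot(np.gradient(run.x) / dt, np.gradient(run.y) / dt))
    )
    # heading of the first in-field displacement
    k = int(np.argmax(seg > 1e-9)) if np.any(seg > 1e-9) else 0
    run.entry_direction_deg = float(
        np.degrees(np.arctan2(run.y[k + 1] - run.y[k], run.x[k + 1] - run.x[k])) % 360.0
    )
    run.straight = bool(run.tortuosity < 1.4)
    return run


def attach_spikes(run: RunRecord, spike_t, spike_phase_deg) -> RunRecord:
    """Attach in-run spikes with their cumulative in-field distance."""
    st = np.asarray(spike_t, dtype=float)
    ph = np.asarray(spike_phase_deg, dtype=float)
    sel = (st >= run.entry_t) & (st <= run.exit_t) & np.isfinite(ph)
    run.spike_t = st[sel]
    run.spike_phase_deg = ph[sel]
    run.spike_dist_cm = np.interp(run.spike_t, run.t, run.cumdist)
    return run


def filter_runs(
    runs,
    min_spikes: int = 4,
    min_cycles: float = 3.0,
    min_instant_speed: float = 1.0,
    apply_robustness: bool = False,
) -> list[RunRecord]:
    """Primary spike-count filter (strictly more than ``min_spikes`` spikes),
    with the optional theta-cycle / instantaneous-speed robustness filter."""
    out = []
    for r in runs:
        if r.n_spikes <= min_spikes:
            continue
        if apply_robustness:
            if np.isfinite(r.n_theta_cycles) and r.n_theta_cycles < min_cycles:
                continue
            if r.min_instant_speed < min_instant_speed:
                continue
        out.append(r)
    return out


def split_halves(run: RunRecord, min_length: float = 60.0):
    """Split a long run at half its path length; spikes at the midpoint go
    to the first half.  Returns (first, second) as (distances, phases) pairs
    with the second half's distances re-zeroed at the midpoint."""
    if not np.isfinite(run.path_length) or run.path_length <= min_length:
        raise ValueError(f"run shorter than {min_length} cm cannot be split")
    half = run.path_length / 2.0
    first = run.spike_dist_cm <= half
    d1, p1 = run.spike_dist_cm[first], run.spike_phase_deg[first]
    d2, p2 = run.spike_dist_cm[~first] - half, run.spike_phase_deg[~first]
    return (d1, p1), (d2, p2)
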