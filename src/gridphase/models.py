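"""Oscillatory-interference (velocity-controlled oscillator) grid-cell models.

Three variants are implemented.  Each "dendritic" oscillator i has angular
frequency

    omega_i(t) = omega_b + beta * s(t) * cos(theta_dir(t) - theta_i),

where omega_b is the baseline (theta) angular frequency, beta the speed
gain, s the running speed and theta_dir the movement direction.  A
voltage-like variable is the superposition of the oscillators' cosines and
spikes are emitted at upward threshold crossings; spike phases are taken
relative to the baseline oscillation.

- Variant 1: three oscillators, preferred directions 60 degrees apart.
  Produces a hexagonal firing pattern but direction-dependent phase coding,
  including phase *recession* along some directions.
- Variant 2: three oscillators 120 degrees apart.  For any movement
  direction at least one oscillator falls below baseline frequency, so the
  phase changes non-monotonically within a field (precess, then recess).
- Variant 3: three pairs of opposed oscillators (six total) with the
  speed-dependent frequency increment half-wave rectified, so no oscillator
  ever falls below the theta frequency.  Phase precession then occurs for
  runs in any direction, with a slope independent of path length,
  tortuosity, eccentricity and speed.

Oscillator phases are obtained by trapezoidal integration of omega_i(t) on
a 1 kHz internal grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .circstats import fit_circular_linear
from .synthetic import Trajectory

__all__ = [
    "VCOModelConfig",
    "ModelOutput",
    "vco_voltage",
    "model_spikes",
    "simulate_model",
    "straight_run",
    "arc_run",
    "model_prediction_suite",
    "pipeline_report",
]

_DEG = np.pi / 180.0


@dataclass
class VCOModelConfig:
    """Configuration of one oscillatory-interference variant."""

    variant: int = 3
    theta_f: float = 8.0              # baseline (theta) frequency, Hz
    beta: float | None = None         # speed gain, rad/cm; None -> variant default
    directions_deg: tuple | None = None
    amplitude: float = 1.0
    threshold: float | None = None    # voltage threshold; None -> variant default
    include_baseline_term: bool = False  # add cos(omega_b t) to the sum
    internal_fs: float = 1000.0
    phase_origin: tuple[float, float] | None = None  # grid vertex; None -> box center

    def __post_init__(self):
        if self.variant not in (1, 2, 3):
            raise ValueError("variant must be 1, 2 or 3")
        if self.directions_deg is None:
            self.directions_deg = {
                1: (0.0, 60.0, 120.0),
                2: (0.0, 120.0, 240.0),
                3: (0.0, 60.0, 120.0),  # each paired with its opposite
            }[self.variant]
        if self.beta is None:
            # beat wavelength 2*pi/beta, chosen to give ~30 cm grid spacing
            self.beta = 0.21
        if self.threshold is None:
            # tuned so threshold-crossing regions approximate ~25 cm fields
            # (variants 1-2: sum of 3 cosines, max 3; variant 3: sum of 6)
            self.threshold = {1: 2.4, 2: 2.4, 3: 3.6}[self.variant]

    @property
    def omega_b(self) -> float:
        return 2 * np.pi * self.theta_f

    def oscillator_directions(self) -> np.ndarray:
        d = np.asarray(self.directions_deg, dtype=float)
        if self.variant == 3:
            d = np.concatenate([d, d + 180.0])
        return d


@dataclass
class ModelOutput:
    t: np.ndarray
    v: np.ndarray
    baseline_phase_deg: np.ndarray = dc_field(repr=False)  # unwrapped
    spike_t: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    spike_phase_deg: np.ndarray = dc_field(default_factory=lambda: np.empty(0))


def vco_voltage(traj: Trajectory, cfg: VCOModelConfig):
    """Voltage trace of the oscillator superposition along a trajectory.

    Oscillator phases are initialized from the start position relative to
    ``phase_origin`` so that a grid vertex sits at the origin (box center by
    default) regardless of where the trajectory begins; thereafter each
    phase is the trapezoidal integral of its velocity-controlled frequency.
    Returns ``(t, v, baseline_unwrapped_deg)`` on the internal fine grid.
    """
    if np.any(np.diff(traj.t) <= 0):
        raise ValueError("trajectory times must be strictly increasing")
    dt = 1.0 / cfg.internal_fs
    t = np.arange(traj.t[0], traj.t[-1], dt)
    x = np.interp(t, traj.t, traj.x)
    y = np.interp(t, traj.t, traj.y)
    dts = np.gradient(t)
    vx = np.gradient(x) / dts
    vy = np.gradient(y) / dts
    speed = np.hypot(vx, vy)
    direction = np.arctan2(vy, vx)

    ox, oy = cfg.phase_origin or (traj.box_size / 2.0, traj.box_size / 2.0)
    # spatial anchoring scale: pair *differences* carry the envelope in
    # variant 3 (effective wavevector beta/2), single phases in variants 1-2
    anchor = cfg.beta if cfg.variant in (1, 2) else cfg.beta / 2.0

    dirs = cfg.oscillator_directions() * _DEG

    def osc_phase(th):
        inc = cfg.beta * speed * np.cos(direction - th)
        if cfg.variant == 3:
            inc = np.maximum(inc, 0.0)  # half-wave rectified increment
        omega = cfg.omega_b + inc
        psi0 = anchor * ((x[0] - ox) * np.cos(th) + (y[0] - oy) * np.sin(th))
        return psi0 + np.concatenate(
            [[0.0], np.cumsum(0.5 * (omega[1:] + omega[:-1]) * np.diff(t))]
        )

    # superposition of the oscillators' cosines (3 for variants 1-2, 6 for
    # variant 3, where the phase difference within each opposed pair evolves
    # with pure displacement and anchors the hexagonal envelope in space)
    v = np.zeros(t.size)
    for th in dirs:
        v += cfg.amplitude * np.cos(osc_phase(th))
    if cfg.include_baseline_term:
        v += cfg.amplitude * np.cos(cfg.omega_b * (t - t[0]))
    baseline = np.degrees(cfg.omega_b * (t - t[0]))
    return t, v, baseline


def model_spikes(t, v, threshold, baseline_unwrapped_deg) -> ModelOutput:
    """Spikes at upward threshold crossings; phases from the baseline.

    The baseline oscillation cos(omega_b t) peaks at phase 90 deg under the
    ascending-zero-crossing convention, so the assigned phase is the
    baseline angle plus 90 deg, wrapped to [0, 360).
    """
    v = np.asarray(v, dtype=float)
    above = v >= threshold
    idx = np.flatnonzero(~above[:-1] & above[1:])
    if idx.size == 0:
        return ModelOutput(t=t, v=v, baseline_phase_deg=baseline_unwrapped_deg)
    frac = (threshold - v[idx]) / (v[idx + 1] - v[idx])
    st = t[idx] + frac * (t[idx + 1] - t[idx])
    base = baseline_unwrapped_deg[idx] + frac * (
        baseline_unwrapped_deg[idx + 1] - baseline_unwrapped_deg[idx]
    )
    return ModelOutput(
        t=t,
        v=v,
        baseline_phase_deg=baseline_unwrapped_deg,
        spike_t=st,
        spike_phase_deg=(base + 90.0) % 360.0,
    )


def simulate_model(traj: Trajectory, cfg: VCOModelConfig) -> ModelOutput:
    t, v, baseline = vco_voltage(traj, cfg)
    return model_spikes(t, v, cfg.threshold, baseline)


# ---------------------------------------------------------------------------
# Probe trajectories for the model-prediction analyses


def straight_run(direction_deg: float, speed: float = 20.0, length: float = 60.0,
                 offset: float = 0.0, center: tuple[float, float] = (0.0, 0.0),
                 fs: float = 200.0) -> Trajectory:
    """Constant-speed straight segment passing at ``offset`` cm from ``center``.

    The run is centered on the closest-approach point so that an offset of 0
    passes exactly through the field center.
    """
    th = direction_deg * _DEG
    n = max(int(round(length / speed * fs)), 2)
    t = np.arange(n) / fs
    s = (t - t[-1] / 2) * speed
    ux, uy = np.cos(th), np.sin(th)
    px, py = -uy, ux  # left normal
    x = center[0] + s * ux + offset * px
    y = center[1] + s * uy + offset * py
    box = 2 * (np.abs(np.concatenate([x, y])).max() + 1)
    return Trajectory(t=t, x=x + box / 2, y=y + box / 2, box_size=box)


def arc_run(direction_deg: float, speed: float = 20.0, length: float = 60.0,
            curvature: float = 0.02, center: tuple[float, float] = (0.0, 0.0),
            fs: float = 200.0) -> Trajectory:
    """Constant-speed circular-arc run through ``center`` (signed curvature 1/cm)."""
    if curvature == 0:
        return straight_run(direction_deg, speed, length, 0.0, center, fs)
    n = max(int(round(length / speed * fs)), 2)
    t = np.arange(n) / fs
    s = (t - t[-1] / 2) * speed
    R = 1.0 / curvature
    ang = s / R
    # arc through the origin with initial heading `direction_deg` at s=0
    xa = R * np.sin(ang)
    ya = R * (1 - np.cos(ang))
    th = direction_deg * _DEG
    x = center[0] + xa * np.cos(th) - ya * np.sin(th)
    y = center[1] + xa * np.sin(th) + ya * np.cos(th)
    box = 2 * (np.abs(np.concatenate([x, y])).max() + 1)
    return Trajectory(t=t, x=x + box / 2, y=y + box / 2, box_size=box)


def _run_fit(out: ModelOutput, traj: Trajectory, min_spikes: int = 4,
             bounds=(-60.0, 60.0), field_radius: float = 12.0):
    """Fit phase vs distance for one probe run's central-field spikes.

    Probe runs cross the grid vertex at the box center; spikes within
    ``field_radius`` of it constitute the field traversal, mirroring how
    the data pipeline restricts spikes to one field mask.  Distance is
    measured along the path from the first in-field spike (the field entry
    stand-in).  None if too few spikes.
    """
    if out.spike_t.size <= min_spikes:
        return None
    seg = np.hypot(np.diff(traj.x), np.diff(traj.y))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    sx = np.interp(out.spike_t, traj.t, traj.x)
    sy = np.interp(out.spike_t, traj.t, traj.y)
    c = traj.box_size / 2.0
    infield = np.hypot(sx - c, sy - c) <= field_radius
    if infield.sum() <= min_spikes:
        return None
    d = np.interp(out.spike_t[infield], traj.t, cum)
    d = d - d[0]
    if np.ptp(d) < 1e-6:
        return None
    return fit_circular_linear(d, out.spike_phase_deg[infield], bounds=bounds)


def pipeline_report(cfg: VCOModelConfig, duration: float = 600.0, seed: int = 0,
                    box: float = 100.0, theta_f: float | None = None) -> dict:
    """Model spikes on a foraging trajectory through the full data pipeline.

    Simulates the model along a random foraging path, builds a synthetic
    LFP at the baseline frequency (so the pipeline's Hilbert phase equals
    the model's baseline phase), and runs field extraction -> runs -> fits
    exactly as for recorded data.  Returns the fits table, gridness, and
    the slope-versus-path-property correlations.
    """
    from .pipeline import analyze_session
    from .synthetic import simulate_foraging
    from .thetaphase import LfpSignal

    traj = simulate_foraging(duration, box, seed=seed)
    out = simulate_model(traj, cfg)
    f0 = theta_f if theta_f is not None else cfg.theta_f
    lt = np.arange(0.0, traj.t[-1] + 0.004, 0.004)
    # cosine baseline: peak at t=0 corresponds to phase 90 deg, matching
    # the model's own baseline-phase bookkeeping
    lfp = LfpSignal(lt, np.cos(2 * np.pi * f0 * lt))
    res = analyze_session(traj, out.spike_t, lfp)
    rep = dict(
        fits=res.fits,
        gridness=float(res.gridness.score),
        n_fields=len(res.fields),
        n_runs=len(res.qualifying_runs),
        complete=len(res.fits) >= 10,
    )
    f = res.fits
    if len(f) >= 3:
        rep["mean_slope"] = float(f["slope"].mean())
        rep["median_r"] = float(f["r"].median())
        for prop, key in (
            ("path_length", "corr_slope_path_length"),
            ("tortuosity", "corr_slope_tortuosity"),
            ("eccentricity", "corr_slope_eccentricity"),
            ("mean_speed", "corr_slope_speed"),
        ):
            rep[key] = float(np.corrcoef(f[prop], f["slope"])[0, 1])
    return rep


def model_prediction_suite(
    cfg: VCOModelConfig,
    directions=tuple(np.arange(0.0, 360.0, 45.0)),
    speeds=(10.0, 20.0, 30.0, 40.0),
    offsets=(0.0, 4.0, 8.0),
    curvatures=(0.01, 0.02, 0.03),
    lengths=(40.0, 60.0, 80.0),
) -> dict:
    """Run the phase-analysis over probe runs and summarize model predictions.

    Probes cover >= 8 directions, several speeds, run lengths, lateral
    offsets (eccentricities) and curvatures (tortuosities) through a grid
    vertex of the model's lattice.  Returns the per-run fit table and the
    slope-versus-property correlations the data analysis also computes.
    For population-level statistics of variant 3 prefer
    :func:`pipeline_report`, which analyses model spikes exactly like
    recorded data.
    """
    rows = []
    for dirn in directions:
        for speed in speeds:
            for offset in offsets:
                for length in lengths:
                    traj = straight_run(dirn, speed=speed, length=length, offset=offset)
                    fit = _run_fit(simulate_model(traj, cfg), traj)
                    if fit is None:
                        continue
                    rows.append(
                        dict(direction=dirn, speed=speed, eccentricity=offset,
                             tortuosity=1.0, slope=fit.slope, r=fit.r, n=fit.n,
                             path_length=length, kind="straight")
                    )
    for dirn in directions[::2]:
        for curv in curvatures:
            traj = arc_run(dirn, speed=20.0, length=60.0, curvature=curv)
            fit = _run_fit(simulate_model(traj, cfg), traj)
            if fit is None:
                continue
            chord = float(np.hypot(traj.x[-1] - traj.x[0], traj.y[-1] - traj.y[0]))
            rows.append(
                dict(direction=dirn, speed=20.0, eccentricity=0.0,
                     tortuosity=60.0 / chord, slope=fit.slope, r=fit.r,
                     n=fit.n, path_length=60.0, kind="arc")
            )

    import pandas as pd

    df = pd.DataFrame(rows)
    report = {"fits": df, "variant": cfg.variant, "complete": True}
    if df.empty or df["direction"].nunique() < 8:
        report["complete"] = False
        return report

    straight = df[df.kind == "straight"]
    report["slope_by_direction"] = straight.groupby("direction")["slope"].mean()
    report["has_recession_direction"] = bool((report["slope_by_direction"] > 0).any())
    for prop in ("speed", "eccentricity", "tortuosity", "path_length"):
        sub = df if prop == "tortuosity" else straight
        if sub[prop].nunique() > 1 and len(sub) > 2:
            c = np.corrcoef(sub[prop], sub["slope"])[0, 1]
        else:
            c = np.nan
        report[f"corr_slope_{prop}"] = float(c)
    return report
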