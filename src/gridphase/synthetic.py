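"""Synthetic trajectories, theta LFP and grid-cell spike trains.

Everything downstream of raw data is testable against known ground truth
generated here: open-field foraging paths in a square box (smooth heading
diffusion, log-normal-ish speed process with median ~19.5 cm/s), linear
track running, a theta-band LFP whose instantaneous frequency performs a
bounded random walk, and inhomogeneous-Poisson grid-cell spikes whose theta
phase follows a configurable precession law

    phi(d) = phi_entry + m * d + wrapped noise,

with d the distance traveled since field entry.  Spikes are generated
against the LFP's *ground-truth* phase (not a filtered estimate), so the
pipeline's phase-assignment error is measurable.  A saturating phase-law
variant caps the total phase range, emulating precession that starts steep
and flattens out within a run.

Hexagonal field centers are built from two lattice vectors 60 degrees
apart; spacing and orientation are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import special

from .thetaphase import LfpSignal

__all__ = [
    "Trajectory",
    "SpeedParams",
    "TurnParams",
    "SyntheticGroundTruth",
    "SyntheticLfp",
    "SpikeTrain",
    "hexagonal_centers",
    "simulate_foraging",
    "simulate_linear_track",
    "simulate_theta_lfp",
    "simulate_grid_spikes",
    "simulate_session",
]

TRACKING_RATE = 50.0   # Hz
LFP_RATE = 250.0       # Hz
_DEG = np.pi / 180.0

#: radius of the 20%-of-peak level set of a Gaussian bump with scale sigma
LEVEL20 = np.sqrt(2.0 * np.log(5.0))


@dataclass
class Trajectory:
    """Tracked head position: times (s) and x, y (cm) in a [0, L]^2 box."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    box_size: float

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.size == self.x.size == self.y.size):
            raise ValueError("t, x, y must have equal length")
        if self.t.size >= 2 and np.any(np.diff(self.t) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        eps = 1e-9
        if self.x.size and (
            self.x.min() < -eps
            or self.x.max() > self.box_size + eps
            or self.y.min() < -eps
            or self.y.max() > self.box_size + eps
        ):
            raise ValueError("positions outside the box")

    def speed(self) -> np.ndarray:
        """Instantaneous speed (cm/s) from central differences."""
        dt = np.gradient(self.t)
        return np.hypot(np.gradient(self.x) / dt, np.gradient(self.y) / dt)

    def path_length(self) -> float:
        return float(np.sum(np.hypot(np.diff(self.x), np.diff(self.y))))


@dataclass
class SpeedParams:
    """Log-speed Ornstein-Uhlenbeck process parameters."""

    median: float = 19.5      # cm/s, median of the stationary distribution
    sigma_log: float = 0.55   # stationary std of log-speed (broad spread)
    tau: float = 1.5          # relaxation time, s


@dataclass
class TurnParams:
    sigma: float = 1.2        # heading diffusion, rad / sqrt(s)
    tau: float = 0.5          # angular-velocity relaxation, s


@dataclass
class SyntheticGroundTruth:
    """Ground truth for grid-cell spike generation."""

    field_centers: list | None = None      # [(x, y)] cm; None -> hex lattice
    field_sigma: float = 7.0               # cm (20%-level diameter ~ 25 cm)
    true_slope: float = -8.0               # deg/cm
    phase_offset_mode: str = "uniform"     # 'uniform' | 'fixed' per run
    entry_phase_deg: float = 180.0         # used when mode == 'fixed'
    phase_noise_kappa: float = 4.0         # von Mises concentration; inf = none
    peak_rate: float = 15.0                # Hz
    theta_f0: float = 8.0                  # Hz
    theta_drift: float = 0.5               # Hz / sqrt(s) random-walk scale
    phase_model: str = "linear"            # 'linear' | 'saturating'
    phase_range_max: float = 210.0         # deg, cap for the saturating law
    grid_spacing: float = 50.0             # cm, hex lattice
    grid_orientation: float = 0.0          # deg

    def __post_init__(self):
        if self.field_sigma <= 0:
            raise ValueError("field_sigma must be positive")
        if not 6.0 <= self.theta_f0 <= 11.0:
            raise ValueError("theta_f0 must lie in the 6-11 Hz theta band")

    @property
    def field_radius(self) -> float:
        """Radius of the 20%-of-peak level set (field border)."""
        return self.field_sigma * LEVEL20

    def centers(self, box_size: float) -> np.ndarray:
        if self.field_centers is not None:
            return np.asarray(self.field_centers, dtype=float)
        return hexagonal_centers(box_size, self.grid_spacing, self.grid_orientation)


@dataclass
class SyntheticLfp:
    """LFP with its ground-truth phase (ascending-zero-crossing convention)."""

    lfp: LfpSignal
    true_phase_deg: np.ndarray       # wrapped, [0, 360)
    true_unwrapped_deg: np.ndarray
    true_freq_hz: np.ndarray


@dataclass
class SpikeTrain:
    """Spikes with per-spike ground truth for test assertions."""

    t: np.ndarray
    true_phase_deg: np.ndarray       # ground-truth LFP phase at spike time
    field_id: np.ndarray             # index into ground-truth centers
    dist_cm: np.ndarray              # distance traveled since field entry
    run_index: np.ndarray            # ground-truth traversal counter
    entry_phase_deg: np.ndarray      # phase offset of the spike's run
    ground_truth: SyntheticGroundTruth = dc_field(repr=False, default=None)


def hexagonal_centers(box_size: float, spacing: float = 50.0, orientation_deg: float = 0.0,
                      offset: tuple[float, float] | None = None) -> np.ndarray:
    """Hexagonal lattice points inside the box (two 60-degree lattice vectors)."""
    th = orientation_deg * _DEG
    v1 = spacing * np.array([np.cos(th), np.sin(th)])
    v2 = spacing * np.array([np.cos(th + np.pi / 3), np.sin(th + np.pi / 3)])
    if offset is None:
        offset = (box_size / 2.0, box_size / 2.0)
    k = int(np.ceil(2 * box_size / spacing)) + 2
    pts = []
    for i in range(-k, k + 1):
        for j in range(-k, k + 1):
            p = np.asarray(offset) + i * v1 + j * v2
            if 0 <= p[0] <= box_size and 0 <= p[1] <= box_size:
                pts.append(p)
    return np.array(pts) if pts else np.empty((0, 2))


def simulate_foraging(
    duration: float,
    box: float = 100.0,
    speed_params: SpeedParams | None = None,
    turn_params: TurnParams | None = None,
    seed: int | None = None,
    fs: float = TRACKING_RATE,
) -> Trajectory:
    """Smooth random foraging path in a square box, sampled at ``fs`` Hz.

    Heading follows an Ornstein-Uhlenbeck angular-velocity process; speed is
    exp of an OU process (log-normal stationary distribution).  Walls
    reflect the heading specularly.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if box <= 0:
        raise ValueError("box size must be positive")
    sp = speed_params or SpeedParams()
    tp = turn_params or TurnParams()
    rng = np.random.default_rng(seed)

    n = int(round(duration * fs))
    dt = 1.0 / fs
    t = np.arange(n) * dt
    x = np.empty(n)
    y = np.empty(n)
    x[0], y[0] = box / 2.0, box / 2.0
    heading = rng.uniform(0, 2 * np.pi)
    mu = np.log(sp.median)
    u = mu if sp.sigma_log == 0 else rng.normal(mu, sp.sigma_log)
    omega = 0.0

    for i in range(1, n):
        # OU log-speed
        if sp.sigma_log > 0:
            u += (mu - u) / sp.tau * dt + sp.sigma_log * np.sqrt(2 * dt / sp.tau) * rng.normal()
        s = np.exp(u)
        # OU angular velocity -> smooth turning
        if tp.sigma > 0:
            omega += -omega / tp.tau * dt + tp.sigma * np.sqrt(2 * dt / tp.tau) * rng.normal()
        heading += omega * dt
        nx = x[i - 1] + s * np.cos(heading) * dt
        ny = y[i - 1] + s * np.sin(heading) * dt
        # specular reflection at walls
        for _ in range(4):
            moved = False
            if nx < 0:
                nx, heading, moved = -nx, np.pi - heading, True
            elif nx > box:
                nx, heading, moved = 2 * box - nx, np.pi - heading, True
            if ny < 0:
                ny, heading, moved = -ny, -heading, True
            elif ny > box:
                ny, heading, moved = 2 * box - ny, -heading, True
            if not moved:
                break
        x[i], y[i] = np.clip(nx, 0, box), np.clip(ny, 0, box)

    return Trajectory(t=t, x=x, y=y, box_size=box)


def simulate_linear_track(
    duration: float,
    track_length: float = 300.0,
    speed_params: SpeedParams | None = None,
    seed: int | None = None,
    fs: float = TRACKING_RATE,
) -> Trajectory:
    """Back-and-forth running on a linear track; y is constant.

    Each lap gets an independent speed draw from the log-normal speed
    distribution (constant within the lap).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if track_length <= 0:
        raise ValueError("track_length must be positive")
    sp = speed_params or SpeedParams()
    rng = np.random.default_rng(seed)

    n = int(round(duration * fs))
    dt = 1.0 / fs
    t = np.arange(n) * dt
    x = np.empty(n)
    pos, direction = 0.0, 1.0
    mu = np.log(sp.median)
    speed = sp.median if sp.sigma_log == 0 else float(np.exp(rng.normal(mu, sp.sigma_log)))
    for i in range(n):
        x[i] = pos
        pos += direction * speed * dt
        while pos < 0 or pos > track_length:
            if pos > track_length:
                pos = 2 * track_length - pos
            else:
                pos = -pos
            direction *= -1
            speed = sp.median if sp.sigma_log == 0 else float(np.exp(rng.normal(mu, sp.sigma_log)))
    y = np.zeros(n)
    return Trajectory(t=t, x=x, y=y, box_size=track_length)


def simulate_theta_lfp(
    t_grid,
    f0: float = 8.0,
    drift: float = 0.5,
    amplitude: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    fs: float = LFP_RATE,
) -> SyntheticLfp:
    """Theta LFP with slowly drifting instantaneous frequency at 250 Hz.

    The instantaneous frequency performs a random walk of scale ``drift``
    Hz/sqrt(s) around ``f0``, reflected at the theta-band edges (6 and 11
    Hz, widened if ``f0`` lies outside).  The voltage is
    amplitude * sin(phase) + white noise, so the ground-truth phase is 0 at
    ascending zero-crossings and 90 deg at peaks.
    """
    if not 1.0 <= f0 <= fs / 2.0:
        raise ValueError(f"f0={f0} outside the representable range [1, {fs / 2}] Hz")
    t_grid = np.asarray(t_grid, dtype=float)
    rng = np.random.default_rng(seed)
    t0, t1 = float(t_grid[0]), float(t_grid[-1])
    n = int(np.floor((t1 - t0) * fs)) + 1
    t = t0 + np.arange(n) / fs
    dt = 1.0 / fs

    lo, hi = min(6.0, f0), max(11.0, f0)
    if drift > 0:
        steps = drift * np.sqrt(dt) * rng.standard_normal(n)
        f = np.empty(n)
        cur = f0
        for i in range(n):
            cur += steps[i]
            # reflect into the band
            while cur < lo or cur > hi:
                cur = 2 * lo - cur if cur < lo else 2 * hi - cur
            f[i] = cur
    else:
        f = np.full(n, f0)

    unwrapped = np.concatenate([[0.0], np.cumsum(0.5 * (f[1:] + f[:-1]) * dt * 360.0)])
    phase = unwrapped % 360.0
    v = amplitude * np.sin(unwrapped * _DEG)
    if noise_sd > 0:
        v = v + noise_sd * rng.standard_normal(n)
    return SyntheticLfp(
        lfp=LfpSignal(t=t, v=v),
        true_phase_deg=phase,
        true_unwrapped_deg=unwrapped,
        true_freq_hz=f,
    )


def _target_phase(gt: SyntheticGroundTruth, entry_phase: float, d: np.ndarray) -> np.ndarray:
    """Ground-truth phase law along distance-in-field d (unwrapped degrees)."""
    if gt.phase_model == "linear":
        return entry_phase + gt.true_slope * d
    if gt.phase_model == "saturating":
        rmax = gt.phase_range_max
        mag = np.abs(gt.true_slope)
        if mag == 0:
            return entry_phase + 0.0 * d
        return entry_phase + np.sign(gt.true_slope) * rmax * (1.0 - np.exp(-mag * d / rmax))
    raise ValueError(f"unknown phase_model {gt.phase_model!r}")


def simulate_grid_spikes(
    traj: Trajectory,
    gt: SyntheticGroundTruth,
    lfp: SyntheticLfp,
    seed: int | None = None,
    internal_fs: float = 1000.0,
) -> SpikeTrain:
    """Grid-cell spikes obeying the ground-truth phase-precession law.

    An inhomogeneous Poisson process with a Gaussian spatial envelope
    around each field center is thinned by a von Mises factor centered on
    the target phase phi_entry + m*d(t), evaluated against the LFP's
    ground-truth phase.  With ``phase_noise_kappa=inf`` spikes are placed
    exactly at the crossings of the target phase (Bernoulli-accepted with
    the spatial envelope), giving noise-free phases.
    """
    if traj.t.size < 2:
        raise ValueError("empty or degenerate trajectory")
    if traj.t[0] < lfp.lfp.t[0] - 1e-9 or traj.t[-1] > lfp.lfp.t[-1] + 1.0 / LFP_RATE + 1e-9:
        raise ValueError("trajectory and LFP must cover the same time span")
    rng = np.random.default_rng(seed)
    centers = gt.centers(traj.box_size)
    if centers.size == 0:
        raise ValueError("no field centers inside the box")

    # fine time grid
    dt = 1.0 / internal_fs
    tf = np.arange(traj.t[0], traj.t[-1], dt)
    xf = np.interp(tf, traj.t, traj.x)
    yf = np.interp(tf, traj.t, traj.y)
    lfp_unwrapped = np.interp(tf, lfp.lfp.t, lfp.true_unwrapped_deg)

    d2 = (xf[:, None] - centers[None, :, 0]) ** 2 + (yf[:, None] - centers[None, :, 1]) ** 2
    nearest = np.argmin(d2, axis=1)
    nearest_d2 = d2[np.arange(tf.size), nearest]
    in_field = nearest_d2 <= gt.field_radius**2
    fid = np.where(in_field, nearest, -1)

    # contiguous single-field traversals
    step = np.hypot(np.diff(xf, prepend=xf[0]), np.diff(yf, prepend=yf[0]))
    cum = np.cumsum(step)
    change = np.flatnonzero(np.diff(fid) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [tf.size]])

    spikes, phases, fids, dists, runids, entries = [], [], [], [], [], []
    run_counter = -1
    noiseless = np.isinf(gt.phase_noise_kappa)
    for s0, s1 in zip(starts, ends):
        f = fid[s0]
        if f < 0:
            continue
        run_counter += 1
        d = cum[s0:s1] - cum[s0]
        entry_phase = (
            gt.entry_phase_deg
            if gt.phase_offset_mode == "fixed"
            else float(rng.uniform(0.0, 360.0))
        )
        target = _target_phase(gt, entry_phase, d)
        env = np.exp(-nearest_d2[s0:s1] / (2 * gt.field_sigma**2))
        lfp_seg = lfp_unwrapped[s0:s1]
        if gt.peak_rate <= 0:
            continue
        if noiseless:
            # spikes at crossings of lfp phase through the target phase
            # spike where the LFP phase crosses the target phase (mod 360)
            g = lfp_seg - target  # both unwrapped
            wraps = np.floor(g / 360.0)
            cross = np.flatnonzero(np.diff(wraps) > 0)
            for c in cross:
                lo_, hi_ = g[c], g[c + 1]
                level = 360.0 * wraps[c + 1]
                frac = (level - lo_) / (hi_ - lo_) if hi_ != lo_ else 0.5
                e = env[c] + frac * (env[c + 1] - env[c])
                accept_p = min(1.0, gt.peak_rate * e / gt.theta_f0)
                if rng.uniform() < accept_p:
                    ts = tf[s0 + c] + frac * dt
                    spikes.append(ts)
                    phases.append((target[c] + frac * (target[c + 1] - target[c])) % 360.0)
                    fids.append(f)
                    dists.append(d[c] + frac * (d[c + 1] - d[c]))
                    runids.append(run_counter)
                    entries.append(entry_phase)
        else:
            kappa = gt.phase_noise_kappa
            delta = (lfp_seg - target) * _DEG
            mod = np.exp(kappa * np.cos(delta)) / special.i0(kappa)
            lam = gt.peak_rate * env * mod
            counts = rng.poisson(lam * dt)
            idx = np.repeat(np.arange(s0, s1), counts[: s1 - s0])
            if idx.size:
                jitter = rng.uniform(0, dt, idx.size)
                nmax = tf.size - 1
                for k, j in zip(idx, jitter):
                    k1 = min(k + 1, nmax)
                    frac = j / dt
                    spikes.append(tf[k] + j)
                    phases.append(
                        (lfp_unwrapped[k] + frac * (lfp_unwrapped[k1] - lfp_unwrapped[k]))
                        % 360.0
                    )
                    fids.append(f)
                    k0 = k - s0
                    k1r = min(k0 + 1, d.size - 1)
                    dists.append(d[k0] + frac * (d[k1r] - d[k0]))
                    runids.append(run_counter)
                    entries.append(entry_phase)

    order = np.argsort(spikes) if spikes else np.array([], dtype=int)
    return SpikeTrain(
        t=np.asarray(spikes, dtype=float)[order],
        true_phase_deg=np.asarray(phases, dtype=float)[order],
        field_id=np.asarray(fids, dtype=int)[order],
        dist_cm=np.asarray(dists, dtype=float)[order],
        run_index=np.asarray(runids, dtype=int)[order],
        entry_phase_deg=np.asarray(entries, dtype=float)[order],
        ground_truth=gt,
    )


def simulate_session(
    duration: float = 600.0,
    box: float = 100.0,
    gt: SyntheticGroundTruth | None = None,
    seed: int | None = None,
    speed_params: SpeedParams | None = None,
    turn_params: TurnParams | None = None,
):
    """Convenience: trajectory + theta LFP + grid spikes with shared seeding.

    Returns ``(traj, lfp, spikes, gt)``.
    """
    gt = gt or SyntheticGroundTruth()
    ss = np.random.SeedSequence(seed)
    s_traj, s_lfp, s_spk = ss.spawn(3)
    traj = simulate_foraging(duration, box, speed_params, turn_params,
                             seed=s_traj.generate_state(1)[0])
    lfp = simulate_theta_lfp(traj.t, f0=gt.theta_f0, drift=gt.theta_drift,
                             seed=s_lfp.generate_state(1)[0])
    spikes = simulate_grid_spikes(traj, gt, lfp, seed=s_spk.generate_state(1)[0])
    return traj, lfp, spikes, gt
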