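"""Instantaneous theta phase from the LFP and spike-phase assignment.

The LFP is band-pass filtered in the theta range (6-11 Hz) with a
zero-phase (forward-backward) Butterworth filter, and the instantaneous
phase is taken from the Hilbert analytic signal.  The phase convention puts
0 deg at the ascending zero-crossing of the oscillation, 90 deg at the
peak, 180 deg at the descending zero-crossing and 270 deg at the trough.
Spikes receive the circularly-interpolated phase at their time stamp.
Intervals where the theta amplitude drops below a floor (default 10% of
the session median) are flagged degenerate and spikes therein excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "LfpSignal",
    "PhaseSeries",
    "bandpass_theta",
    "instantaneous_phase",
    "assign_spike_phases",
    "count_theta_cycles",
]

THETA_BAND = (6.0, 11.0)


@dataclass
class LfpSignal:
    """Single-channel field potential: times (s) and voltage samples."""

    t: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.size != self.v.size:
            raise ValueError("t and v must have equal length")
        if self.t.size >= 2 and np.any(np.diff(self.t) <= 0):
            raise ValueError("LFP time base must be strictly increasing")
        if not np.all(np.isfinite(self.v)):
            raise ValueError("LFP contains non-finite samples")

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))


@dataclass
class PhaseSeries:
    """Instantaneous phase (deg, [0,360)), frequency (Hz) and amplitude.

    ``unwrapped_deg`` is the monotone unwrapped phase used for circular
    interpolation and theta-cycle counting; ``valid`` flags samples whose
    amplitude exceeds the degeneracy floor.
    """

    t: np.ndarray
    phase_deg: np.ndarray
    freq_hz: np.ndarray
    amplitude: np.ndarray
    unwrapped_deg: np.ndarray = field(repr=False)
    valid: np.ndarray = field(repr=False)


def bandpass_theta(lfp: LfpSignal, band=THETA_BAND, order: int = 4) -> LfpSignal:
    """Zero-phase Butterworth band-pass; same length and time base."""
    fs = lfp.fs
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"band {band} outside (0, Nyquist={fs / 2:g}) Hz")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return LfpSignal(lfp.t, signal.sosfiltfilt(sos, lfp.v))


def instantaneous_phase(filtered: LfpSignal, amp_floor_frac: float = 0.1) -> PhaseSeries:
    """Analytic-signal phase under the ascending-zero-crossing convention.

    For v = A*sin(omega*t) the phase at t=0 is 0 deg (ascending slope) and
    the peak maps to 90 deg; equivalently phase = angle(hilbert(v)) + 90 deg.
    """
    v = filtered.v
    analytic = signal.hilbert(v)
    amplitude = np.abs(analytic)
    # angle of analytic(cos) is the cosine phase; shift so peak -> 90 deg
    raw = np.unwrap(np.angle(analytic))
    unwrapped = np.degrees(raw) + 90.0
    phase = unwrapped % 360.0
    dt = np.gradient(filtered.t)
    freq = np.gradient(unwrapped / 360.0) / dt

    floor = amp_floor_frac * np.median(amplitude)
    valid = amplitude > floor
    return PhaseSeries(
        t=filtered.t,
        phase_deg=phase,
        freq_hz=freq,
        amplitude=amplitude,
        unwrapped_deg=unwrapped,
        valid=valid,
    )


def assign_spike_phases(spike_t, phase: PhaseSeries):
    """Per-spike phase by circular interpolation of the unwrapped phase.

    Returns ``(phases_deg, used)`` where ``used`` marks spikes inside the
    series' span and in non-degenerate intervals; excluded spikes get NaN.
    """
    st = np.asarray(spike_t, dtype=float)
    in_span = (st >= phase.t[0]) & (st <= phase.t[-1])
    phases = np.full(st.size, np.nan)
    if in_span.any():
        unwrapped = np.interp(st[in_span], phase.t, phase.unwrapped_deg)
        phases[in_span] = unwrapped % 360.0
    # exclude spikes falling in low-amplitude (degenerate) intervals
    ok = in_span.copy()
    if not phase.valid.all() and in_span.any():
        idx = np.searchsorted(phase.t, st[in_span]).clip(0, phase.t.size - 1)
        left = np.maximum(idx - 1, 0)
        good = phase.valid[idx] & phase.valid[left]
        sub = np.flatnonzero(in_span)
        ok[sub[~good]] = False
        phases[sub[~good]] = np.nan
    return phases, ok


def count_theta_cycles(phase: PhaseSeries, t0: float, t1: float) -> float:
    """Number of theta cycles in [t0, t1]: unwrapped phase span / 360."""
    if t1 < t0:
        raise ValueError("t1 must be >= t0")
    u0, u1 = np.interp([t0, t1], phase.t, phase.unwrapped_deg)
    return float((u1 - u0) / 360.0)
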