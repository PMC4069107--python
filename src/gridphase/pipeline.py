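"""End-to-end single-run phase-precession analysis.

Ties together rate-map/field extraction, theta-phase estimation, run
segmentation and circular-linear fitting, and provides the derived
analyses: pooled-versus-single-run fits, phase range versus path length,
phase-versus-time fits with the speed cone, grouped comparisons, and
spike-phase preference histograms.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats

from . import circstats, ratemap, runs as runs_mod, thetaphase
from .circstats import PrecessionFit, fit_circular_linear
from .ratemap import FiringField, GridnessResult, RateMap
from .runs import RunRecord
from .synthetic import Trajectory
from .thetaphase import LfpSignal, PhaseSeries

__all__ = [
    "StudyConfig",
    "SessionResult",
    "analyze_session",
    "pooled_fit",
    "phase_range_curve",
    "time_vs_distance_fits",
    "group_compare",
    "first_spike_and_preference",
]


@dataclass
class StudyConfig:
    """All analysis thresholds, at their standard defaults."""

    kernel_width: float = 5.0            # cm, rate-map Gaussian sigma
    bin_size: float = 1.0                # cm
    global_frac: float = 0.20            # field seed threshold (x overall peak)
    local_frac: float = 0.20             # field growth threshold (x field peak)
    min_area: float = 200.0              # cm^2
    max_circumference: float = 160.0     # cm
    min_gridness: float = 0.0
    min_spikes: int = 4                  # runs must have MORE than this
    slope_bounds: tuple = (-60.0, 60.0)  # deg/cm
    # phase-vs-time fits: bounds kept below half the theta aliasing distance
    # (spikes recur ~once per theta cycle, so slopes ~360*f_theta apart are
    # indistinguishable); +-1500 deg/s covers speed x distance-slope products
    time_slope_bounds: tuple = (-1500.0, 1500.0)
    time_grid_step: float = 2.5          # deg/s
    theta_band: tuple = (6.0, 11.0)      # Hz
    straight_tortuosity: float = 1.4
    long_run_threshold: float = 60.0     # cm, first/second-half analysis
    min_cycles: float = 3.0
    min_instant_speed: float = 1.0       # cm/s
    apply_robustness: bool = False
    central_fields_only: bool = False
    seed: int | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


@dataclass
class SessionResult:
    """Everything the pipeline derives from one recording session."""

    config: StudyConfig
    rate_map: RateMap
    fields: list
    gridness: GridnessResult
    phase: PhaseSeries
    runs: list                     # all completed runs (per field, flattened)
    qualifying_runs: list          # runs passing the spike-count filter
    fits: pd.DataFrame             # one row per qualifying run
    passes_gridness: bool = True
    n_spikes_used: int = 0
    n_spikes_excluded: int = 0

    def summary(self) -> str:
        f = self.fits
        lines = [
            "Single-run phase-precession session summary",
            "=" * 46,
            f"fields detected          {len(self.fields):>8d}",
            f"gridness score           {self.gridness.score:>8.3f}",
            f"runs (all / qualifying)  {len(self.runs):>4d} / {len(self.qualifying_runs)}",
        ]
        if len(f):
            lines += [
                f"median slope [deg/cm]    {f.slope.median():>8.2f}",
                f"mean slope [deg/cm]      {f.slope.mean():>8.2f} +- {f.slope.sem():.2f}",
                f"median correlation r     {f.r.median():>8.3f}",
            ]
        return "\n".join(lines)


def analyze_session(
    traj: Trajectory,
    spike_t,
    lfp: LfpSignal,
    config: StudyConfig | None = None,
    metadata: dict | None = None,
) -> SessionResult:
    """Run the full pipeline on one session (one unit).

    ``metadata`` (e.g. ``{"layer": "II"}``) is copied into every row of the
    fits table for downstream grouping.
    """
    cfg = config or StudyConfig()
    spike_t = np.asarray(spike_t, dtype=float)

    rm = ratemap.compute_rate_map(traj, spike_t, cfg.kernel_width, cfg.bin_size)
    fields = ratemap.segment_fields(
        rm, cfg.global_frac, cfg.local_frac, cfg.min_area, cfg.max_circumference
    )
    if cfg.central_fields_only:
        fields = [f for f in fields if not f.touches_boundary]
    grid = ratemap.gridness(rm)
    passes = grid.score >= cfg.min_gridness

    filtered = thetaphase.bandpass_theta(lfp, cfg.theta_band)
    phase = thetaphase.instantaneous_phase(filtered)
    spike_phases, used = thetaphase.assign_spike_phases(spike_t, phase)

    all_runs: list[RunRecord] = []
    for fld in fields:
        for run in runs_mod.segment_runs(traj, fld, rm):
            run = runs_mod.path_metrics(run, fld)
            if run is None:
                continue
            run.straight = bool(run.tortuosity < cfg.straight_tortuosity)
            runs_mod.attach_spikes(run, spike_t, spike_phases)
            run.n_theta_cycles = thetaphase.count_theta_cycles(
                phase, run.entry_t, run.exit_t
            )
            all_runs.append(run)

    qualifying = runs_mod.filter_runs(
        all_runs,
        min_spikes=cfg.min_spikes,
        min_cycles=cfg.min_cycles,
        min_instant_speed=cfg.min_instant_speed,
        apply_robustness=cfg.apply_robustness,
    )

    rows = []
    for i, run in enumerate(qualifying):
        fit_d = fit_circular_linear(
            run.spike_dist_cm, run.spike_phase_deg, bounds=cfg.slope_bounds
        )
        trel = run.spike_t - run.entry_t
        fit_t = fit_circular_linear(
            trel, run.spike_phase_deg, bounds=cfg.time_slope_bounds,
            grid_step=cfg.time_grid_step, abscissa="time",
        )
        row = dict(
            run_id=i,
            field_id=run.field_id,
            n_spikes=run.n_spikes,
            slope=fit_d.slope,
            offset_deg=fit_d.offset_deg,
            r=fit_d.r,
            p=fit_d.p_value,
            resultant=fit_d.resultant,
            bound_hit=fit_d.bound_hit,
            slope_time=fit_t.slope,
            r_time=fit_t.r,
            path_length=run.path_length,
            tortuosity=run.tortuosity,
            eccentricity=run.eccentricity,
            mean_speed=run.mean_speed,
            entry_direction=run.entry_direction_deg,
            n_theta_cycles=run.n_theta_cycles,
            straight=run.straight,
            touches_boundary=run.touches_boundary,
        )
        if metadata:
            row.update(metadata)
        rows.append(row)
    fits = pd.DataFrame(rows)

    return SessionResult(
        config=cfg,
        rate_map=rm,
        fields=fields,
        gridness=grid,
        phase=phase,
        runs=all_runs,
        qualifying_runs=qualifying,
        fits=fits,
        passes_gridness=passes,
        n_spikes_used=int(used.sum()),
        n_spikes_excluded=int((~used).sum()),
    )


def pooled_fit(field_runs, bounds=(-60.0, 60.0)) -> PrecessionFit:
    """Single circular-linear fit over all runs of one field, concatenating
    spikes with their per-run cumulative distance as abscissa."""
    field_runs = [r for r in field_runs if r.n_spikes > 0]
    if len(field_runs) < 2:
        raise ValueError("pooled fit needs at least 2 runs with spikes")
    d = np.concatenate([r.spike_dist_cm for r in field_runs])
    p = np.concatenate([r.spike_phase_deg for r in field_runs])
    return fit_circular_linear(d, p, bounds=bounds)


def phase_range_curve(fits: pd.DataFrame, bin_width: float = 10.0) -> pd.DataFrame:
    """Mean total phase shift |m| * path_length binned by path length."""
    if fits.empty:
        return pd.DataFrame(columns=["length_bin", "mean_range", "sem", "n"])
    rng = np.abs(fits["slope"]) * fits["path_length"]
    bins = np.floor(fits["path_length"] / bin_width).astype(int)
    rows = []
    for b, grp in rng.groupby(bins):
        if len(grp) == 0:
            continue
        rows.append(
            dict(
                length_bin=(b + 0.5) * bin_width,
                mean_range=float(grp.mean()),
                sem=float(grp.sem()) if len(grp) > 1 else np.nan,
                n=int(len(grp)),
            )
        )
    return pd.DataFrame(rows)


def time_vs_distance_fits(fits: pd.DataFrame, percentiles=(5.0, 95.0)) -> dict:
    """Speed-cone statistics of the (distance-slope, time-slope) scatter.

    Any line through the origin of the scatter corresponds to a constant
    speed m_time = v * m_dist; the cone between the lower/upper speed
    percentiles should contain most points.
    """
    ok = fits[np.abs(fits["slope"]) > 1e-9]
    if ok.empty:
        return dict(fraction_in_cone=np.nan, v_lo=np.nan, v_hi=np.nan, n=0)
    ratio = ok["slope_time"] / ok["slope"]
    v_lo, v_hi = np.percentile(ok["mean_speed"], percentiles)
    inside = (ratio >= v_lo) & (ratio <= v_hi)
    return dict(
        fraction_in_cone=float(inside.mean()),
        v_lo=float(v_lo),
        v_hi=float(v_hi),
        n=int(len(ok)),
        median_speed=float(ok["mean_speed"].median()),
    )


def group_compare(fits: pd.DataFrame, label: str) -> dict:
    """Compare slopes (means; t-test / one-way ANOVA) and correlations
    (medians; Wilcoxon rank-sum) across groups defined by a metadata label.

    Slopes are compared with parametric tests on means; correlation
    coefficients come from strongly skewed distributions, so their medians
    are compared with the rank-sum test.
    """
    groups = {k: g for k, g in fits.groupby(label) if len(g) >= 2}
    out = {
        "groups": {
            k: dict(
                n=int(len(g)),
                slope_mean=float(g["slope"].mean()),
                slope_sem=float(g["slope"].sem()),
                r_median=float(g["r"].median()),
            )
            for k, g in groups.items()
        },
        "pairwise": {},
    }
    keys = list(groups)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            a, b = groups[keys[i]], groups[keys[j]]
            t_p = float(stats.ttest_ind(a["slope"], b["slope"]).pvalue)
            rs_p = float(stats.ranksums(a["r"], b["r"]).pvalue)
            out["pairwise"][(keys[i], keys[j])] = dict(slope_t_p=t_p, r_ranksum_p=rs_p)
    if len(keys) >= 2:
        out["slope_anova_p"] = float(
            stats.f_oneway(*[g["slope"] for g in groups.values()]).pvalue
        )
    return out


def first_spike_and_preference(qualifying_runs, n_bins: int = 10) -> dict:
    """Normalized phase histograms (all spikes and first-in-field spikes)
    with vector strength and Rayleigh uniformity p for each."""
    all_ph = np.concatenate(
        [r.spike_phase_deg for r in qualifying_runs if r.n_spikes > 0]
    ) if qualifying_runs else np.empty(0)
    first_ph = np.array(
        [r.spike_phase_deg[0] for r in qualifying_runs if r.n_spikes > 0]
    )
    edges = np.linspace(0.0, 360.0, n_bins + 1)

    def block(ph):
        if ph.size < 2:
            return dict(hist=np.zeros(n_bins), vector_strength=np.nan,
                        rayleigh_p=np.nan, n=int(ph.size))
        h, _ = np.histogram(ph, bins=edges)
        vs, p = circstats.rayleigh_test(ph)
        return dict(hist=h / h.sum(), vector_strength=vs, rayleigh_p=p, n=int(ph.size))

    return dict(bin_edges=edges, all_spikes=block(all_ph), first_spikes=block(first_ph))
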