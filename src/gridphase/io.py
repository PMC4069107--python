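"""Plain-text readers and writers for the pipeline's data formats.

Tracking: TSV with columns t, x, y (s, cm).  Spikes: TSV with column t.
LFP: TSV with columns t, v.  Ground truth: JSON sidecar.  Outputs: rate
map as dense TSV with a header comment, field masks as run-length-encoded
TSV plus a JSON field summary, run and fit tables as TSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ratemap import FiringField, RateMap
from .synthetic import SpikeTrain, SyntheticGroundTruth, SyntheticLfp, Trajectory
from .thetaphase import LfpSignal, PhaseSeries

__all__ = [
    "write_tracking", "read_tracking",
    "write_spikes", "read_spikes",
    "write_lfp", "read_lfp",
    "write_ground_truth", "read_ground_truth",
    "write_rate_map", "write_fields", "write_phase_series",
    "write_runs_table", "write_fits",
]


def write_tracking(path, traj: Trajectory) -> None:
    df = pd.DataFrame({"t": traj.t, "x": traj.x, "y": traj.y})
    with open(path, "w") as fh:
        fh.write(f"# box_size_cm\t{traj.box_size}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_tracking(path) -> Trajectory:
    box = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            box = float(first.strip().split("\t")[1])
        else:
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t")
    if box is None:
        box = float(np.ceil(max(df.x.max(), df.y.max())))
    return Trajectory(t=df.t.to_numpy(), x=df.x.to_numpy(), y=df.y.to_numpy(), box_size=box)


def write_spikes(path, spike_t) -> None:
    pd.DataFrame({"t": np.asarray(spike_t, dtype=float)}).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def read_spikes(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").t.to_numpy()


def write_lfp(path, lfp: LfpSignal) -> None:
    pd.DataFrame({"t": lfp.t, "v": lfp.v}).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def read_lfp(path) -> LfpSignal:
    df = pd.read_csv(path, sep="\t")
    return LfpSignal(t=df.t.to_numpy(), v=df.v.to_numpy())


def write_ground_truth(path, gt: SyntheticGroundTruth, spikes: SpikeTrain | None = None) -> None:
    d = dataclasses.asdict(gt)
    if d.get("field_centers") is not None:
        d["field_centers"] = [list(map(float, c)) for c in d["field_centers"]]
    d["phase_noise_kappa"] = (
        "inf" if np.isinf(gt.phase_noise_kappa) else gt.phase_noise_kappa
    )
    if spikes is not None:
        d["spike_truth"] = dict(
            t=spikes.t.tolist(),
            true_phase_deg=spikes.true_phase_deg.tolist(),
            field_id=spikes.field_id.tolist(),
            dist_cm=spikes.dist_cm.tolist(),
            run_index=spikes.run_index.tolist(),
        )
    Path(path).write_text(json.dumps(d, indent=2))


def read_ground_truth(path) -> SyntheticGroundTruth:
    d = json.loads(Path(path).read_text())
    d.pop("spike_truth", None)
    if d.get("phase_noise_kappa") == "inf":
        d["phase_noise_kappa"] = np.inf
    return SyntheticGroundTruth(**d)


def write_rate_map(path, rm: RateMap) -> None:
    with open(path, "w") as fh:
        fh.write(f"# bin_size_cm\t{rm.bin_size}\torigin\t{rm.x_edges[0]}\t{rm.y_edges[0]}\n")
        np.savetxt(fh, rm.rate, delimiter="\t", fmt="%.4f")


def write_fields(prefix, fields: list[FiringField]) -> None:
    """Write field summaries (JSON) and run-length-encoded masks (TSV)."""
    prefix = Path(prefix)
    summary = [
        dict(
            field_id=f.field_id,
            peak_x=f.peak_xy[0],
            peak_y=f.peak_xy[1],
            peak_rate=f.peak_rate,
            area_cm2=f.area,
            circumference_cm=f.circumference,
            touches_boundary=f.touches_boundary,
        )
        for f in fields
    ]
    prefix.with_suffix(".json").write_text(json.dumps(summary, indent=2))
    rows = []
    for f in fields:
        for iy in range(f.mask.shape[0]):
            xs = np.flatnonzero(f.mask[iy])
            if xs.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(xs) > 1)
            starts = np.concatenate([[0], breaks + 1])
            ends = np.concatenate([breaks, [xs.size - 1]])
            for s, e in zip(starts, ends):
                rows.append((f.field_id, iy, int(xs[s]), int(xs[e])))
    pd.DataFrame(rows, columns=["field_id", "row", "col_start", "col_end"]).to_csv(
        prefix.with_suffix(".tsv"), sep="\t", index=False
    )


def write_phase_series(path, ps: PhaseSeries) -> None:
    pd.DataFrame(
        {"t": ps.t, "phase_deg": ps.phase_deg, "freq_hz": ps.freq_hz,
         "amplitude": ps.amplitude}
    ).to_csv(path, sep="\t", index=False, float_format="%.4f")


def write_runs_table(path, runs) -> None:
    rows = [
        dict(
            field_id=r.field_id, entry_t=r.entry_t, exit_t=r.exit_t,
            path_length=r.path_length, tortuosity=r.tortuosity,
            eccentricity=r.eccentricity, mean_speed=r.mean_speed,
            entry_direction_deg=r.entry_direction_deg, n_spikes=r.n_spikes,
            n_theta_cycles=r.n_theta_cycles, straight=r.straight,
            touches_boundary=r.touches_boundary,
        )
        for r in runs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.4f")


def write_fits(path, fits: pd.DataFrame) -> None:
    fits.to_csv(path, sep="\t", index=False, float_format="%.5f")
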