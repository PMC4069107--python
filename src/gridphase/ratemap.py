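"""Occupancy-normalized firing-rate maps, firing-field segmentation, gridness.

Rate maps use 1 cm x 1 cm bins by default.  Spike-count and occupancy maps
are smoothed separately with the same Gaussian kernel (sigma 5 cm) before
the ratio is taken, which keeps spike mass conserved and avoids edge
artifacts; unvisited bins are NaN (missing), never zero.

Firing fields are segmented in two stages: connected components above 20%
of the map's overall peak seed the candidate fields, and each candidate is
then grown by geodesic dilation into bins above 20% of its own peak rate.
Fields with area < 200 cm^2 or circumference > 160 cm are excluded.

The gridness score is the classic rotational-symmetry statistic of the
spatial autocorrelogram: min(corr at 60, 120 deg) - max(corr at 30, 90,
150 deg) over an annulus that excludes the central peak and contains the
six surrounding peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "RateMap",
    "FiringField",
    "GridnessResult",
    "compute_rate_map",
    "segment_fields",
    "circumference",
    "gridness",
    "spatial_autocorrelogram",
]


@dataclass
class RateMap:
    """Firing-rate grid (Hz) with its occupancy (s); row = y bin, col = x bin.

    ``rate`` is NaN on unvisited bins.  ``occupancy`` is the smoothed
    occupancy used in the normalization; ``occupancy_raw`` is unsmoothed.
    """

    rate: np.ndarray
    occupancy: np.ndarray
    occupancy_raw: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    bin_size: float

    @property
    def peak_rate(self) -> float:
        return float(np.nanmax(self.rate))

    def bin_center(self, iy: int, ix: int) -> tuple[float, float]:
        return (
            float(0.5 * (self.x_edges[ix] + self.x_edges[ix + 1])),
            float(0.5 * (self.y_edges[iy] + self.y_edges[iy + 1])),
        )


@dataclass
class FiringField:
    """One segmented firing field on the rate-map grid."""

    mask: np.ndarray                 # boolean over rate-map bins
    peak_xy: tuple[float, float]     # cm, location of maximum rate in mask
    peak_rate: float                 # Hz
    area: float                      # cm^2
    circumference: float             # cm
    touches_boundary: bool
    field_id: int = 0


@dataclass
class GridnessResult:
    score: float
    rotation_correlations: dict      # degrees -> Pearson r over the annulus
    inner_radius: float              # cm
    outer_radius: float              # cm
    degenerate: bool = False


def compute_rate_map(
    traj,
    spike_t,
    kernel_width: float = 5.0,
    bin_size: float = 1.0,
    smooth_after_division: bool = False,
) -> RateMap:
    """Occupancy-normalized rate map from a trajectory and spike times.

    Spike positions are interpolated from the tracking samples.  By default
    the spike-count and occupancy histograms are smoothed separately and
    then divided; ``smooth_after_division=True`` instead smooths the raw
    ratio (the alternative reading of the construction).
    """
    spike_t = np.asarray(spike_t, dtype=float)
    if spike_t.size and (spike_t.min() < traj.t[0] - 1e-9 or spike_t.max() > traj.t[-1] + 1e-9):
        raise ValueError("spikes outside the trajectory time span")

    L = traj.box_size
    nbins = int(round(L / bin_size))
    edges = np.linspace(0.0, L, nbins + 1)

    dt = np.diff(traj.t)
    dt = np.append(dt, dt[-1] if dt.size else 0.0)
    occ, _, _ = np.histogram2d(traj.y, traj.x, bins=[edges, edges], weights=dt)
    if occ.sum() <= 0:
        raise ValueError("trajectory produced no occupancy")

    sx = np.interp(spike_t, traj.t, traj.x)
    sy = np.interp(spike_t, traj.t, traj.y)
    spk, _, _ = np.histogram2d(sy, sx, bins=[edges, edges])

    sigma = kernel_width / bin_size
    if smooth_after_division:
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = np.where(occ > 0, spk / np.where(occ > 0, occ, 1.0), np.nan)
        rate = _smooth_nan(raw, sigma)
        occ_s = ndimage.gaussian_filter(occ, sigma, mode="reflect")
    else:
        # reflect boundaries conserve total mass under the symmetric kernel
        occ_s = ndimage.gaussian_filter(occ, sigma, mode="reflect")
        spk_s = ndimage.gaussian_filter(spk, sigma, mode="reflect")
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(occ_s > 1e-12, spk_s / np.where(occ_s > 0, occ_s, 1.0), np.nan)

    return RateMap(
        rate=rate,
        occupancy=occ_s,
        occupancy_raw=occ,
        x_edges=edges,
        y_edges=edges,
        bin_size=bin_size,
    )


def _smooth_nan(a, sigma):
    """Gaussian smoothing that treats NaN as missing (normalized convolution)."""
    m = np.isfinite(a)
    filled = np.where(m, a, 0.0)
    num = ndimage.gaussian_filter(filled, sigma, mode="reflect")
    den = ndimage.gaussian_filter(m.astype(float), sigma, mode="reflect")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den < 1e-6] = np.nan
    return out


def circumference(mask, bin_size: float = 1.0) -> float:
    """Perimeter traced along bin boundaries (4-connectivity edges)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no circumference")
    edges = 0
    padded = np.pad(mask, 1, constant_values=False)
    for shift_axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        nb = np.roll(padded, shift, axis=shift_axis)
        edges += int(np.sum(padded & ~nb))
    return edges * bin_size


_STRUCT8 = np.ones((3, 3), dtype=bool)


def segment_fields(
    rm: RateMap,
    global_frac: float = 0.20,
    local_frac: float = 0.20,
    min_area: float = 200.0,
    max_circumference: float = 160.0,
) -> list[FiringField]:
    """Two-stage threshold segmentation of firing fields.

    Stage 1: 8-connected components of bins above ``global_frac`` times the
    overall peak.  Stage 2: each component is extended by geodesic dilation
    restricted to bins above ``local_frac`` times that component's own peak,
    iterated to stability; bins reachable from more than one seed are
    assigned to the component whose seed is nearest.  Exclusion rules on
    area and circumference are then applied.
    """
    rate = rm.rate
    finite = np.isfinite(rate)
    if not finite.any() or np.nanmax(rate) <= 0:
        return []
    peak = np.nanmax(rate)
    seed = finite & (rate >= global_frac * peak)
    if not seed.any():
        return []
    labels, nlab = ndimage.label(seed, structure=_STRUCT8)

    # geodesic dilation of each seed within its own local-threshold support
    grown = []
    for lab in range(1, nlab + 1):
        comp = labels == lab
        local_peak = np.nanmax(np.where(comp, rate, -np.inf))
        allowed = finite & (rate >= local_frac * local_peak)
        cur = comp
        while True:
            nxt = ndimage.binary_dilation(cur, structure=_STRUCT8) & allowed
            if np.array_equal(nxt, cur):
                break
            cur = nxt
        grown.append(cur)

    # resolve overlaps: contested bins go to the nearest seed component
    owner = np.zeros(rate.shape, dtype=int)
    claim_count = np.zeros(rate.shape, dtype=int)
    for i, g in enumerate(grown, start=1):
        claim_count += g
        owner[g & (owner == 0)] = i
    contested = claim_count > 1
    if contested.any():
        dists = np.stack(
            [ndimage.distance_transform_edt(~(labels == i)) for i in range(1, nlab + 1)]
        )
        claim = np.stack(grown)
        dists = np.where(claim, dists, np.inf)
        owner[contested] = np.argmin(dists[:, contested], axis=0) + 1

    fields = []
    ny, nx = rate.shape
    for lab in range(1, nlab + 1):
        mask = owner == lab
        if not mask.any():
            continue
        # re-split can disconnect a mask; keep the piece containing the seed
        sub, nsub = ndimage.label(mask, structure=_STRUCT8)
        if nsub > 1:
            seed_labs = np.unique(sub[(labels == lab) & (sub > 0)])
            mask = np.isin(sub, seed_labs)
        area = float(mask.sum()) * rm.bin_size**2
        circ = circumference(mask, rm.bin_size)
        if area < min_area or circ > max_circumference:
            continue
        masked = np.where(mask & finite, rate, -np.inf)
        iy, ix = np.unravel_index(int(np.argmax(masked)), rate.shape)
        rows, cols = np.nonzero(mask)
        touches = bool(
            rows.min() == 0 or cols.min() == 0 or rows.max() == ny - 1 or cols.max() == nx - 1
        )
        fields.append(
            FiringField(
                mask=mask,
                peak_xy=rm.bin_center(iy, ix),
                peak_rate=float(rate[iy, ix]),
                area=area,
                circumference=circ,
                touches_boundary=touches,
            )
        )
    fields.sort(key=lambda f: -f.peak_rate)
    for i, f in enumerate(fields):
        f.field_id = i
    return fields


def spatial_autocorrelogram(rate: np.ndarray, min_overlap: int = 20) -> np.ndarray:
    """Pearson spatial autocorrelation for every 2-D lag, missing-aware.

    Unvisited (NaN) bins are excluded pairwise-complete; lags supported by
    fewer than ``min_overlap`` bin pairs are NaN.
    """
    m = np.isfinite(rate).astype(float)
    z = np.where(np.isfinite(rate), rate, 0.0)

    def xcorr(a, b):
        return signal.fftconvolve(a, b[::-1, ::-1], mode="full")

    n = xcorr(m, m)
    sx = xcorr(z, m)
    sy = xcorr(m, z)
    sxx = xcorr(z * z, m)
    syy = xcorr(m, z * z)
    sxy = xcorr(z, z)

    with np.errstate(invalid="ignore", divide="ignore"):
        num = n * sxy - sx * sy
        den = np.sqrt((n * sxx - sx**2) * (n * syy - sy**2))
        r = num / den
    r[np.round(n) < min_overlap] = np.nan
    r[~np.isfinite(r)] = np.nan
    return np.clip(r, -1.0, 1.0)


def _radial_profile(ac):
    cy, cx = (np.array(ac.shape) - 1) / 2.0
    yy, xx = np.indices(ac.shape)
    rr = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    rmax = int(rr.max())
    prof = np.full(rmax + 1, np.nan)
    ri = np.round(rr).astype(int)
    for k in range(rmax + 1):
        vals = ac[(ri == k) & np.isfinite(ac)]
        if vals.size:
            prof[k] = vals.mean()
    return prof


def gridness(rm: RateMap, min_overlap: int = 20) -> GridnessResult:
    """Gridness score of a rate map's spatial autocorrelogram.

    Annulus: inner radius at the first local minimum of the radially
    averaged autocorrelogram (excludes the central peak); outer radius at
    1.25 times the mean distance of the six peaks nearest the center.  If
    six surrounding peaks cannot be identified the result is flagged
    degenerate and a fallback outer radius of 2.5x the inner is used.
    """
    ac = spatial_autocorrelogram(rm.rate, min_overlap=min_overlap)
    cy, cx = (np.array(ac.shape) - 1) / 2.0
    prof = _radial_profile(ac)
    # lags beyond ~70% of the map rest on too little overlap; ignore them
    # (together with min_overlap this rejects the corner artifacts while
    # keeping six-peak rings up to ~ 0.7x the box size detectable)
    r_valid = 0.7 * min(rm.rate.shape)

    # provisional central-peak radius: where the radial profile first falls
    # below 0.2 (the central peak has decayed)
    below = np.flatnonzero(np.isfinite(prof[: int(r_valid)]) & (prof[: int(r_valid)] < 0.2))
    r_central = int(below[0]) if below.size else max(2, int(r_valid) // 4)

    # surrounding peaks: strict local maxima outside the central peak
    # (footprint excludes the center so plateaus do not count as peaks)
    filled = np.where(np.isfinite(ac), ac, -np.inf)
    ring_fp = np.ones((3, 3), dtype=bool)
    ring_fp[1, 1] = False
    local_max = filled > ndimage.maximum_filter(filled, footprint=ring_fp)
    yy, xx = np.indices(ac.shape)
    rr = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    cand = local_max & np.isfinite(ac) & (rr > r_central) & (rr <= r_valid) & (ac > 0.1)
    ys, xs = np.nonzero(cand)

    degenerate = False
    if ys.size >= 6:
        d = rr[ys, xs]
        ring = float(np.mean(d[np.argsort(d)[:6]]))
        outer = 1.25 * ring
        # inner radius: first local minimum of the profile inside the ring
        inner = None
        for k in range(1, min(int(ring), prof.size - 1)):
            if (
                np.isfinite(prof[k - 1 : k + 2]).all()
                and prof[k] <= prof[k - 1]
                and prof[k] <= prof[k + 1]
            ):
                inner = k
                break
        if inner is None:
            inner = r_central
    else:
        inner = r_central
        outer = 2.5 * r_central
        degenerate = True
    outer = min(outer, r_valid)
    if outer <= inner + 1:
        outer = inner + 2
        degenerate = True

    annulus = (rr >= inner) & (rr <= outer)
    corrs = {}
    for ang in (30, 60, 90, 120, 150):
        rot = ndimage.rotate(np.where(np.isfinite(ac), ac, 0.0), ang, reshape=False, order=1)
        rot_mask = (
            ndimage.rotate(np.isfinite(ac).astype(float), ang, reshape=False, order=1) > 0.99
        )
        ok = annulus & np.isfinite(ac) & rot_mask
        if ok.sum() < min_overlap:
            corrs[ang] = np.nan
            degenerate = True
            continue
        a, b = ac[ok], rot[ok]
        sa, sb = a.std(), b.std()
        if sa < 1e-12 or sb < 1e-12:
            corrs[ang] = 0.0
            degenerate = True
        else:
            corrs[ang] = float(np.corrcoef(a, b)[0, 1])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        score = float(
            min(corrs[60], corrs[120]) - max(corrs[30], corrs[90], corrs[150])
        )
    bin_size = rm.bin_size
    return GridnessResult(
        score=score,
        rotation_correlations=corrs,
        inner_radius=inner * bin_size,
        outer_radius=outer * bin_size,
        degenerate=degenerate,
    )
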