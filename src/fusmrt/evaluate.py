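"""Accuracy metrics for reconstructed temperature series.

Implements the evaluation protocol of the phantom experiments: temporal
alignment of the faster subsampled series to the truth k-space-center times
by per-voxel linear interpolation, RMSE at the hottest truth voxel (HV) and
over voxel-time masks where the truth exceeds 15 % / 85 % of its hottest
voxel, FWHM of focal profiles by linear interpolation on the zero-filled
grid, and per-axis focal-spot offsets between volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .thermal import TemperatureSeries

__all__ = [
    "MetricsReport",
    "align_temporal",
    "rmse_report",
    "fwhm_profile",
    "focal_offset",
    "mean_sd",
]


@dataclass
class MetricsReport:
    """RMSE triplet with the thresholds that defined the masks (degC)."""

    rmse_hv: float
    rmse_15: float
    rmse_85: float
    thresholds: tuple[float, float]
    hottest_voxel: tuple[int, int, int]
    n_15: int = 0
    n_85: int = 0
    fwhm: dict = field(default_factory=dict)
    focal_offsets: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"rmse_hv": self.rmse_hv, "rmse_15": self.rmse_15,
                "rmse_85": self.rmse_85,
                "threshold_15": self.thresholds[0],
                "threshold_85": self.thresholds[1]}


def align_temporal(sub_series: TemperatureSeries, truth_center_times) -> TemperatureSeries:
    """Linearly interpolate the subsampled series to the truth
    k-space-center times (queries beyond the series span clamp to the
    nearest frame)."""
    if len(sub_series) < 2:
        raise ValueError("temporal alignment needs at least 2 frames")
    tq = np.asarray(truth_center_times, dtype=float)
    ts = sub_series.times
    idx = np.clip(np.searchsorted(ts, tq) - 1, 0, len(ts) - 2)
    t0, t1 = ts[idx], ts[idx + 1]
    w = np.clip((tq - t0) / (t1 - t0), 0.0, 1.0)  # clamp = end extension
    frames = ((1.0 - w)[:, None, None, None] * sub_series.frames[idx]
              + w[:, None, None, None] * sub_series.frames[idx + 1])
    return TemperatureSeries(frames=frames, times=tq,
                             spacing=sub_series.spacing, origin=sub_series.origin)


def rmse_report(recon_series: TemperatureSeries, truth_series: TemperatureSeries,
                thresholds_frac=(0.15, 0.85), per_frame_masks: bool = False) -> MetricsReport:
    """HV / 15 % / 85 % RMSE of a reconstruction against truth.

    The recon is first aligned to the truth frame times if they differ.  The
    hottest voxel and the thresholds are derived from the truth over all
    frames; with ``per_frame_masks`` the 15 %/85 % masks are recomputed per
    frame from the same global thresholds' defining fractions.
    """
    if not np.array_equal(recon_series.times, truth_series.times):
        recon_series = align_temporal(recon_series, truth_series.times)
    r = np.asarray(recon_series.frames, dtype=float)
    t = np.asarray(truth_series.frames, dtype=float)
    if r.shape != t.shape:
        raise ValueError("recon and truth series must share a grid")
    peak_map = t.max(axis=0)
    hv = np.unravel_index(np.argmax(peak_map), peak_map.shape)  # lexicographic tie-break
    hot = float(peak_map[hv])
    thr = tuple(f * hot for f in thresholds_frac)
    err = r - t
    rmse_hv = float(np.sqrt(np.mean(err[(slice(None),) + hv] ** 2)))

    def masked_rmse(threshold: float) -> tuple[float, int]:
        mask = t > threshold if per_frame_masks else \
            np.broadcast_to(peak_map > threshold, t.shape)
        n = int(mask.sum())
        if n == 0:
            return float("nan"), 0
        return float(np.sqrt(np.mean(err[mask] ** 2))), n

    rmse_15, n15 = masked_rmse(thr[0])
    rmse_85, n85 = masked_rmse(thr[1])
    return MetricsReport(rmse_hv=rmse_hv, rmse_15=rmse_15, rmse_85=rmse_85,
                         thresholds=thr, hottest_voxel=tuple(int(i) for i in hv),
                         n_15=n15, n_85=n85)


def _half_crossing(profile: np.ndarray, peak_idx: int, half: float,
                   direction: int) -> float:
    """Fractional index of the half-maximum crossing on one side of the peak
    (linear interpolation between the bracketing samples)."""
    i = peak_idx
    while 0 <= i + direction < profile.size:
        j = i + direction
        if profile[j] <= half:
            frac = (profile[i] - half) / (profile[i] - profile[j])
            return i + direction * frac
        i = j
    raise ValueError("half maximum not crossed inside the grid")


def fwhm_profile(volume: np.ndarray, axis: int, through_point=None,
                 spacing: float = 1.0) -> float:
    """FWHM (in units of ``spacing``) of the 1D profile along ``axis``
    through ``through_point`` (default: the hottest voxel, ties broken by
    lowest lexicographic index), with half-maximum crossings located by
    linear interpolation."""
    volume = np.asarray(volume, dtype=float)
    if through_point is None:
        through_point = np.unravel_index(np.argmax(volume), volume.shape)
    sl = list(through_point)
    sl[axis] = slice(None)
    profile = volume[tuple(sl)]
    peak_idx = int(through_point[axis])
    peak = profile[peak_idx]
    if peak <= 0:
        raise ValueError("profile peak must be positive")
    half = peak / 2.0
    left = _half_crossing(profile, peak_idx, half, -1)
    right = _half_crossing(profile, peak_idx, half, +1)
    return float((right - left) * spacing)


def focal_offset(volume_a: np.ndarray, volume_b: np.ndarray, spacing) -> np.ndarray:
    """Per-axis distance (same units as ``spacing``) between the argmax of
    two volumes on a common grid; ties broken lexicographically."""
    a = np.asarray(volume_a)
    b = np.asarray(volume_b)
    if a.shape != b.shape:
        raise ValueError("volumes must share a grid")
    if not a.any() or not b.any():
        raise ValueError("cannot locate a focus in an all-zero volume")
    ia = np.unravel_index(np.argmax(a), a.shape)
    ib = np.unravel_index(np.argmax(b), b.shape)
    return (np.asarray(ia, dtype=float) - np.asarray(ib)) * np.asarray(spacing, dtype=float)


def mean_sd(values) -> tuple[float, float]:
    """Sample mean and SD (ddof=1) across repeated sonications."""
    v = np.asarray(values, dtype=float)
    return float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0
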