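"""Valid-sample processing: binocular fusion, upsampling, zero-phase smoothing.

After filtering, each eye's valid samples form a nonuniform series with
gaps.  This module fuses the two eyes into a "mean pupil size" series via
a dynamically interpolated left–right offset, resamples onto a uniform
high-rate grid, smooths with a forward–backward (zero-phase) low-pass
Butterworth filter, and finally re-masks grid points that were
interpolated across unacceptably large gaps.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .io_model import InsufficientDataError

logger = logging.getLogger("pupilprep")


@dataclass
class ProcessingSettings:
    target_rate_hz: float = 1000.0
    lowpass_cutoff_hz: float = 4.0
    max_interp_gap_ms: float = 250.0
    lowpass_order: int = 1  # per direction; applied forward-backward

    def __post_init__(self) -> None:
        if min(self.target_rate_hz, self.lowpass_cutoff_hz, self.max_interp_gap_ms) <= 0:
            raise ValueError("processing settings must be positive")
        if self.lowpass_order < 1:
            raise ValueError("lowpass_order must be >= 1")
        if self.target_rate_hz <= 2 * self.lowpass_cutoff_hz:
            raise ValueError("target rate must exceed twice the low-pass cutoff")


@dataclass
class SmoothSignal:
    """Uniform-rate smoothed diameter series with masked (NaN) regions."""

    t: np.ndarray
    d: np.ndarray
    rate_hz: float
    source: str = "mean"  # "left" / "right" / "mean"
    over_gap: np.ndarray = field(default=None)  # grid points interpolated over a masked gap

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if self.t.size != self.d.size:
            raise ValueError("t and d must align")
        if self.over_gap is None:
            self.over_gap = np.zeros(self.t.size, dtype=bool)
        if self.t.size > 1:
            dt = np.diff(self.t)
            if not np.allclose(dt, 1.0 / self.rate_hz, rtol=1e-6, atol=1e-9):
                raise ValueError("grid spacing must be uniform at 1/rate_hz")

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.d)


@dataclass
class FusedSeries:
    """Binocular fusion result with per-point provenance."""

    t: np.ndarray
    d: np.ndarray
    provenance: np.ndarray  # "both" / "left" / "right"


def combine_eyes(
    t_left: np.ndarray,
    d_left: np.ndarray,
    t_right: np.ndarray,
    d_right: np.ndarray,
) -> FusedSeries:
    """Fuse two eyes' valid samples into a mean-pupil series.

    Where both eyes have (near-)simultaneous samples the fused value is
    simply (L+R)/2.  Where only one eye has data, the signed size offset
    o = R - L — measured at double-coverage points and linearly
    interpolated (held constant beyond the ends) — supplies the missing
    half: mean = L + o/2 or R - o/2.  Pupil sizes of the two eyes are
    highly correlated locally, which is what makes this offset model
    reasonable.
    """
    t_left = np.asarray(t_left, dtype=float)
    d_left = np.asarray(d_left, dtype=float)
    t_right = np.asarray(t_right, dtype=float)
    d_right = np.asarray(d_right, dtype=float)

    if t_left.size == 0 and t_right.size == 0:
        raise InsufficientDataError("no valid samples in either eye")
    if t_right.size == 0:
        return FusedSeries(t_left, d_left.copy(), np.full(t_left.size, "left", dtype=object))
    if t_left.size == 0:
        return FusedSeries(t_right, d_right.copy(), np.full(t_right.size, "right", dtype=object))

    # Double-coverage pairing: mutual nearest neighbors within half the
    # median inter-sample interval; beyond that a point is single-coverage.
    intervals = np.concatenate([np.diff(t_left), np.diff(t_right)])
    tol = 0.5 * np.median(intervals) if intervals.size else np.inf

    idx_r = np.clip(np.searchsorted(t_right, t_left), 0, t_right.size - 1)
    idx_r_prev = np.clip(idx_r - 1, 0, t_right.size - 1)
    use_prev = np.abs(t_right[idx_r_prev] - t_left) < np.abs(t_right[idx_r] - t_left)
    nearest_r = np.where(use_prev, idx_r_prev, idx_r)

    idx_l = np.clip(np.searchsorted(t_left, t_right), 0, t_left.size - 1)
    idx_l_prev = np.clip(idx_l - 1, 0, t_left.size - 1)
    use_prev_l = np.abs(t_left[idx_l_prev] - t_right) < np.abs(t_left[idx_l] - t_right)
    nearest_l = np.where(use_prev_l, idx_l_prev, idx_l)

    li = np.arange(t_left.size)
    mutual = (nearest_l[nearest_r] == li) & (
        np.abs(t_right[nearest_r] - t_left) <= tol
    )
    pair_l = li[mutual]
    pair_r = nearest_r[mutual]

    if pair_l.size == 0:
        warnings.warn(
            "no double-coverage points: left-right offset unidentifiable; "
            "falling back to the eye with more valid samples",
            stacklevel=2,
        )
        if t_left.size >= t_right.size:
            return FusedSeries(t_left, d_left.copy(), np.full(t_left.size, "left", dtype=object))
        return FusedSeries(t_right, d_right.copy(), np.full(t_right.size, "right", dtype=object))

    t_pair = 0.5 * (t_left[pair_l] + t_right[pair_r])
    mean_pair = 0.5 * (d_left[pair_l] + d_right[pair_r])
    offset = d_right[pair_r] - d_left[pair_l]

    lone_l = np.setdiff1d(li, pair_l, assume_unique=True)
    lone_r = np.setdiff1d(np.arange(t_right.size), pair_r, assume_unique=True)

    # np.interp holds the end values constant outside the sampled range.
    o_at_l = np.interp(t_left[lone_l], t_pair, offset)
    o_at_r = np.interp(t_right[lone_r], t_pair, offset)

    t_all = np.concatenate([t_pair, t_left[lone_l], t_right[lone_r]])
    d_all = np.concatenate(
        [mean_pair, d_left[lone_l] + o_at_l / 2.0, d_right[lone_r] - o_at_r / 2.0]
    )
    prov = np.concatenate(
        [
            np.full(t_pair.size, "both", dtype=object),
            np.full(lone_l.size, "left", dtype=object),
            np.full(lone_r.size, "right", dtype=object),
        ]
    )
    order = np.argsort(t_all, kind="stable")
    t_all, d_all, prov = t_all[order], d_all[order], prov[order]
    keep = np.ones(t_all.size, dtype=bool)
    keep[1:] = np.diff(t_all) > 0
    return FusedSeries(t_all[keep], d_all[keep], prov[keep])


def upsample(
    t_valid: np.ndarray, d_valid: np.ndarray, settings: ProcessingSettings
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate valid samples onto a uniform grid.

    The grid spans [first, last] valid timestamp at ``target_rate_hz``;
    no extrapolation beyond the data span.
    """
    t_valid = np.asarray(t_valid, dtype=float)
    d_valid = np.asarray(d_valid, dtype=float)
    if t_valid.size < 2:
        raise InsufficientDataError("upsampling needs at least 2 valid samples")
    step = 1.0 / settings.target_rate_hz
    n = int(np.floor((t_valid[-1] - t_valid[0]) / step + 1e-9)) + 1
    grid = t_valid[0] + step * np.arange(n)
    return grid, np.interp(grid, t_valid, d_valid)


def lowpass_zero_phase(d: np.ndarray, settings: ProcessingSettings) -> np.ndarray:
    """Zero-phase low-pass filter a uniform series (forward–backward Butterworth).

    Forward-backward application cancels the phase response, so event
    timing is preserved; the DC gain is exactly 1.
    """
    d = np.asarray(d, dtype=float)
    b, a = butter(
        settings.lowpass_order,
        settings.lowpass_cutoff_hz,
        btype="low",
        fs=settings.target_rate_hz,
    )
    padlen = 3 * max(len(a), len(b))
    if d.size <= 3 * padlen:
        raise InsufficientDataError(
            f"series of {d.size} points too short for stable zero-phase filtering"
        )
    return filtfilt(b, a, d)


def mask_large_gaps(
    grid: np.ndarray,
    d: np.ndarray,
    t_valid: np.ndarray,
    settings: ProcessingSettings,
    source: str = "mean",
) -> SmoothSignal:
    """Mask grid points interpolated across raw gaps larger than the limit.

    A grid point lying strictly between two consecutive raw valid samples
    whose separation exceeds ``max_interp_gap_ms`` carries interpolated,
    not measured, information and is set missing.
    """
    grid = np.asarray(grid, dtype=float)
    d = np.asarray(d, dtype=float).copy()
    t_valid = np.asarray(t_valid, dtype=float)
    over_gap = np.zeros(grid.size, dtype=bool)
    max_gap_s = settings.max_interp_gap_ms / 1000.0
    if t_valid.size >= 2:
        gaps = np.diff(t_valid)
        for i in np.flatnonzero(gaps > max_gap_s):
            over_gap |= (grid > t_valid[i]) & (grid < t_valid[i + 1])
    d[over_gap] = np.nan
    return SmoothSignal(t=grid, d=d, rate_hz=settings.target_rate_hz, source=source, over_gap=over_gap)


def process_series(
    t_valid: np.ndarray,
    d_valid: np.ndarray,
    settings: ProcessingSettings,
    source: str = "mean",
) -> SmoothSignal:
    """Full chain on one series: upsample → zero-phase smooth → mask gaps."""
    grid, up = upsample(t_valid, d_valid, settings)
    smooth = lowpass_zero_phase(up, settings)
    return mask_large_gaps(grid, smooth, t_valid, settings, source=source)
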