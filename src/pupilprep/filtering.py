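"""Raw-sample artifact rejection for pupil-size series.

Five stages, applied per eye in order, each seeing only the samples that
survived the previous ones:

1. **range** — diameters outside a physiologically feasible window
   (default 1.5–9 mm) are impossible measurements.
2. **speed** — samples whose dilation speed (the larger of the absolute
   normalized changes toward either neighbor) exceeds a robust
   median + n·MAD threshold; catches blink flanks and lone spikes.
3. **gap_edge** — samples within a margin (50 ms) of data gaps longer
   than a minimum (75 ms); eyelid occlusion biases sizes near blinks.
4. **deviation** — multipass rejection of samples deviating strongly
   from a smooth trend line through the currently valid data, with the
   same median + n·MAD rule applied to the absolute deviations; catches
   clustered outliers that defeat the speed filter.  Later passes rebuild
   the trend and re-test every sample the first pass considered, so
   samples dragged out by a nearby cluster can be reinstated.
5. **sparsity** — short isolated runs of samples (< 50 ms) surrounded by
   gaps (> 40 ms) are glitches, not pupil data.

Thresholds are data-relative (robust statistics of the series itself),
so they adapt across eyetrackers and sampling rates; the multiplier n
has no universal best value and should be tuned per dataset.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np

from .io_model import InsufficientDataError, RawRecording, ValidityMask
from .processing import ProcessingSettings, lowpass_zero_phase, upsample

logger = logging.getLogger("pupilprep")

DEVIATION_STAGE_PREFIX = "deviation_pass_"


@dataclass
class FilterSettings:
    """Tunable parameters of the raw-data filter (defaults in mm / ms / Hz)."""

    range_min_mm: float = 1.5
    range_max_mm: float = 9.0
    speed_mad_multiplier: float = 16.0
    gap_edge_margin_ms: float = 50.0
    gap_min_duration_ms: float = 75.0
    deviation_mad_multiplier: float = 16.0
    deviation_passes: int = 2
    trendline_cutoff_hz: float = 4.0
    trendline_rate_hz: float = 1000.0
    sparsity_split_gap_ms: float = 40.0
    sparsity_min_section_ms: float = 50.0
    min_threshold_epsilon: float = 0.0  # floor added when MAD degenerates to 0

    def __post_init__(self) -> None:
        if self.range_min_mm >= self.range_max_mm:
            raise ValueError("range_min_mm must be < range_max_mm")
        for name in (
            "speed_mad_multiplier",
            "gap_edge_margin_ms",
            "gap_min_duration_ms",
            "deviation_mad_multiplier",
            "trendline_cutoff_hz",
            "trendline_rate_hz",
            "sparsity_split_gap_ms",
            "sparsity_min_section_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.deviation_passes < 1:
            raise ValueError("deviation_passes must be >= 1")
        if self.min_threshold_epsilon < 0:
            raise ValueError("min_threshold_epsilon must be >= 0")


def compute_dilation_speed(t: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Per-sample dilation speed in mm/s.

    The speed at sample i is the maximum absolute size change toward the
    preceding or succeeding sample, each normalized by its time step —
    robust to nonuniform sampling.  Endpoints use their single neighbor.
    """
    t = np.asarray(t, dtype=float)
    d = np.asarray(d, dtype=float)
    if t.size < 2:
        raise InsufficientDataError("dilation speed needs at least 2 samples")
    step = np.abs(np.diff(d) / np.diff(t))
    speed = np.empty(t.size)
    speed[0] = step[0]
    speed[-1] = step[-1]
    if t.size > 2:
        speed[1:-1] = np.maximum(step[:-1], step[1:])
    return speed


def mad_threshold(x: np.ndarray, multiplier: float, epsilon: float = 0.0) -> float:
    """Robust outlier threshold: median(x) + multiplier * MAD(x).

    MAD is the median absolute deviation from the median.  Used for both
    dilation speeds and absolute trend-line deviations.  ``epsilon`` is an
    optional floor for the degenerate MAD = 0 case (default keeps the
    plain formula).
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("mad_threshold needs a non-empty series")
    if multiplier <= 0:
        raise ValueError("multiplier must be > 0")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    thr = med + multiplier * mad
    if epsilon:
        thr = max(thr, med + epsilon)
    return float(thr)


def filter_range(d: np.ndarray, settings: FilterSettings) -> np.ndarray:
    """Stage mask: True where the diameter lies inside the feasible range (bounds inclusive)."""
    d = np.asarray(d, dtype=float)
    mask = np.ones(d.size, dtype=bool)
    present = ~np.isnan(d)
    mask[present] = (d[present] >= settings.range_min_mm) & (
        d[present] <= settings.range_max_mm
    )
    return mask


def filter_speed_outliers(
    t: np.ndarray,
    d: np.ndarray,
    settings: FilterSettings,
    incoming: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Reject dilation-speed outliers among currently valid samples.

    Returns (stage mask, threshold used).  The mask is True everywhere
    except at valid samples whose speed strictly exceeds the threshold.
    """
    t = np.asarray(t, dtype=float)
    d = np.asarray(d, dtype=float)
    if incoming is None:
        incoming = ~np.isnan(d)
    mask = np.ones(t.size, dtype=bool)
    idx = np.flatnonzero(incoming)
    if idx.size < 2:
        return mask, float("nan")
    speed = compute_dilation_speed(t[idx], d[idx])
    thr = mad_threshold(speed, settings.speed_mad_multiplier, settings.min_threshold_epsilon)
    mask[idx[speed > thr]] = False
    return mask, thr


def reject_gap_edges(
    t: np.ndarray, present: np.ndarray, settings: FilterSettings
) -> np.ndarray:
    """Reject samples bordering long gaps in the present-sample pattern.

    A gap is the open interval between two consecutive present samples
    separated by more than ``gap_min_duration_ms``; present samples whose
    distance to the nearer gap boundary is at most ``gap_edge_margin_ms``
    are rejected (the bordering samples themselves included).  The
    recording's start and end are not themselves gap boundaries, but a
    missing region at the start (or end) of the sample array is a gap
    with only a trailing (or leading) edge.
    """
    t = np.asarray(t, dtype=float)
    present = np.asarray(present, dtype=bool)
    mask = np.ones(t.size, dtype=bool)
    idx = np.flatnonzero(present)
    if idx.size < 2:
        return mask
    tv = t[idx]
    margin = settings.gap_edge_margin_ms / 1000.0
    min_gap = settings.gap_min_duration_ms / 1000.0
    near = np.zeros(tv.size, dtype=bool)
    for g in np.flatnonzero(np.diff(tv) > min_gap):
        start, end = tv[g], tv[g + 1]
        near |= ((tv >= start - margin) & (tv <= start)) | (
            (tv >= end) & (tv <= end + margin)
        )
    if tv[0] - t[0] > min_gap:  # missing run at the array start
        near |= tv <= tv[0] + margin
    if t[-1] - tv[-1] > min_gap:  # missing run at the array end
        near |= tv >= tv[-1] - margin
    mask[idx[near]] = False
    return mask


def build_trendline(
    t_valid: np.ndarray,
    d_valid: np.ndarray,
    settings: FilterSettings,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth trend line through valid samples, evaluable anywhere by interpolation.

    Valid samples are linearly interpolated onto a uniform grid and
    low-pass filtered with the same zero-phase smoother used for the
    final signal (cutoff ``trendline_cutoff_hz``).  Returns (grid, trend).
    """
    t_valid = np.asarray(t_valid, dtype=float)
    d_valid = np.asarray(d_valid, dtype=float)
    if t_valid.size < 2:
        raise InsufficientDataError("trend line needs at least 2 valid samples")
    psettings = ProcessingSettings(
        target_rate_hz=settings.trendline_rate_hz,
        lowpass_cutoff_hz=settings.trendline_cutoff_hz,
    )
    if grid is None:
        grid, up = upsample(t_valid, d_valid, psettings)
    else:
        grid = np.asarray(grid, dtype=float)
        up = np.interp(grid, t_valid, d_valid)
    trend = lowpass_zero_phase(up, psettings)
    return grid, trend


def evaluate_trendline(grid: np.ndarray, trend: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.interp(t, grid, trend)


def filter_trendline_deviation(
    t: np.ndarray,
    d: np.ndarray,
    incoming: np.ndarray,
    settings: FilterSettings,
) -> tuple[np.ndarray, list[np.ndarray], list[float]]:
    """Multipass trend-line deviation filter.

    Pass k builds a trend from the currently valid samples, scores the
    absolute deviation of every sample in the pass-1 scope, and rejects
    those above median + n·MAD of these deviations.  Because later passes
    re-test the full scope against a cleaner trend, a sample rejected
    early (its deviation inflated by a neighboring artifact cluster
    "pulling away" the trend) can be reinstated.

    Returns (final stage mask, per-pass verdict masks, per-pass thresholds).
    """
    t = np.asarray(t, dtype=float)
    d = np.asarray(d, dtype=float)
    scope = np.asarray(incoming, dtype=bool)
    valid = scope.copy()
    pass_verdicts: list[np.ndarray] = []
    thresholds: list[float] = []
    for _ in range(settings.deviation_passes):
        if valid.sum() < 2:
            break
        try:
            grid, trend = build_trendline(t[valid], d[valid], settings)
        except InsufficientDataError:
            break
        dev = np.abs(d[scope] - evaluate_trendline(grid, trend, t[scope]))
        thr = mad_threshold(dev, settings.deviation_mad_multiplier, settings.min_threshold_epsilon)
        valid = scope.copy()
        valid[np.flatnonzero(scope)[dev > thr]] = False
        pass_verdicts.append(valid.copy())
        thresholds.append(thr)
    mask = np.ones(t.size, dtype=bool)
    mask[scope & ~valid] = False
    return mask, pass_verdicts, thresholds


def filter_sparsity(
    t: np.ndarray, current: np.ndarray, settings: FilterSettings
) -> np.ndarray:
    """Reject temporally isolated sample islands.

    The valid-sample sequence is split wherever consecutive valid samples
    are separated by more than ``sparsity_split_gap_ms``; resulting
    sections spanning less than ``sparsity_min_section_ms`` (first to
    last timestamp) are rejected wholesale.
    """
    t = np.asarray(t, dtype=float)
    current = np.asarray(current, dtype=bool)
    mask = np.ones(t.size, dtype=bool)
    idx = np.flatnonzero(current)
    if idx.size == 0:
        return mask
    tv = t[idx]
    split_gap = settings.sparsity_split_gap_ms / 1000.0
    min_span = settings.sparsity_min_section_ms / 1000.0
    boundaries = np.flatnonzero(np.diff(tv) > split_gap) + 1
    for section in np.split(np.arange(idx.size), boundaries):
        if tv[section[-1]] - tv[section[0]] < min_span:
            mask[idx[section]] = False
    return mask


@dataclass
class FilterReport:
    """Per-eye record of what each stage rejected and the thresholds used."""

    eye: str
    n_samples: int
    n_present: int
    stage_rejections: dict
    thresholds: dict
    settings: dict
    n_valid: int

    def to_dict(self) -> dict:
        return asdict(self)


def run_filter_pipeline(
    rec: RawRecording, settings: FilterSettings | None = None
) -> tuple[dict[str, ValidityMask], dict[str, FilterReport]]:
    """Apply all filter stages to each recorded eye.

    Stage order: range → speed → gap_edge → deviation (multipass) →
    sparsity.  Each stage only sees samples still valid, except that the
    deviation filter may reinstate samples within its own scope.  Returns
    per-eye validity masks and reports.
    """
    if settings is None:
        settings = FilterSettings()
    masks: dict[str, ValidityMask] = {}
    reports: dict[str, FilterReport] = {}
    t = rec.timestamps
    for eye in rec.eyes:
        d = rec.eye(eye)
        present = ~np.isnan(d)
        vm = ValidityMask(t.size, present=present)
        rejections: dict[str, int] = {}
        thresholds: dict[str, float] = {}

        layer = filter_range(d, settings)
        vm.add_layer("range", layer)
        rejections["range"] = int((present & ~layer).sum())

        cur = vm.combined
        layer, thr = filter_speed_outliers(t, d, settings, incoming=cur)
        vm.add_layer("speed", layer)
        rejections["speed"] = int((cur & ~layer).sum())
        thresholds["speed_mm_per_s"] = thr

        cur = vm.combined
        layer = reject_gap_edges(t, cur, settings)
        vm.add_layer("gap_edge", layer)
        rejections["gap_edge"] = int((cur & ~layer).sum())

        cur = vm.combined
        dev_mask, verdicts, dev_thrs = filter_trendline_deviation(t, d, cur, settings)
        finally_rejected = cur & ~dev_mask
        # Per-pass layers record which pass flagged each finally-rejected
        # sample; their AND equals the final deviation verdict, so the
        # combined-mask invariant survives multipass reinstatement.
        for k, verdict in enumerate(verdicts, start=1):
            layer_k = np.ones(t.size, dtype=bool)
            layer_k[finally_rejected & ~verdict] = False
            vm.add_layer(f"{DEVIATION_STAGE_PREFIX}{k}", layer_k)
        if not verdicts:
            vm.add_layer(f"{DEVIATION_STAGE_PREFIX}1", np.ones(t.size, dtype=bool))
        rejections["deviation"] = int(finally_rejected.sum())
        thresholds["deviation_mm"] = dev_thrs

        cur = vm.combined
        layer = filter_sparsity(t, cur, settings)
        vm.add_layer("sparsity", layer)
        rejections["sparsity"] = int((cur & ~layer).sum())

        n_valid = int(vm.combined.sum())
        if n_valid == 0:
            logger.warning("all %s-eye samples rejected", eye)
        masks[eye] = vm
        reports[eye] = FilterReport(
            eye=eye,
            n_samples=int(t.size),
            n_present=int(present.sum()),
            stage_rejections=rejections,
            thresholds=thresholds,
            settings=asdict(settings),
            n_valid=n_valid,
        )
        logger.info(
            "filter[%s]: %d present → %d valid; rejections %s",
            eye,
            present.sum(),
            n_valid,
            rejections,
        )
    return masks, reports
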