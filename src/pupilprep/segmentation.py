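"""Segment-wise summarization of the smoothed pupil signal.

Windows are half-open [t_start, t_end) on the uniform grid, so
contiguous segments partition the grid points exactly once.  Grid points
the signal does not cover (a segment reaching past the recorded span)
count as missing, which makes the missing-data percentage a faithful
data-sufficiency measure for segment rejection.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .io_model import SegmentTable
from .processing import SmoothSignal

METRIC_COLUMNS = [
    "segment_id",
    "label",
    "mean_mm",
    "max_mm",
    "min_mm",
    "sd_mm",
    "missing_pct",
    "n_grid_points",
    "rejected",
]


def _window_values(signal: SmoothSignal, t_start: float, t_end: float):
    """Values of the nominal grid in [t_start, t_end).

    The nominal grid extends the signal's grid virtually in both
    directions; points outside the recorded span are missing.
    Returns (values of covered points incl. NaN, total nominal points).
    """
    step = 1.0 / signal.rate_hz
    t0 = signal.t[0]
    k_first = int(np.ceil((t_start - t0) / step - 1e-9))
    k_last = int(np.ceil((t_end - t0) / step - 1e-9))  # exclusive
    n_total = max(k_last - k_first, 0)
    lo = min(max(k_first, 0), signal.t.size)
    hi = min(max(k_last, 0), signal.t.size)
    return signal.d[lo:hi], n_total


def summarize_segments(
    signal: SmoothSignal,
    segments: SegmentTable,
    max_missing_pct: float,
) -> pd.DataFrame:
    """Descriptive metrics per segment: mean/max/min/sd diameter and missing %.

    Segments whose missing percentage exceeds ``max_missing_pct`` are
    flagged rejected (never silently dropped).  A segment fully outside
    the signal span yields missing_pct = 100.
    """
    rows = []
    for i in range(len(segments)):
        vals, n_total = _window_values(signal, segments.t_start[i], segments.t_end[i])
        data = vals[~np.isnan(vals)]
        n_missing = n_total - data.size
        missing_pct = 100.0 * n_missing / n_total if n_total else 100.0
        rows.append(
            {
                "segment_id": int(segments.segment_id[i]),
                "label": segments.label[i],
                "mean_mm": float(data.mean()) if data.size else np.nan,
                "max_mm": float(data.max()) if data.size else np.nan,
                "min_mm": float(data.min()) if data.size else np.nan,
                "sd_mm": float(data.std(ddof=1)) if data.size >= 2 else np.nan,
                "missing_pct": missing_pct,
                "n_grid_points": n_total,
                "rejected": bool(missing_pct > max_missing_pct),
            }
        )
    df = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    if segments.trial_id is not None:
        df["trial_id"] = segments.trial_id
    return df


def bin_timecourse(
    signal: SmoothSignal,
    t_start: float,
    t_end: float,
    bin_ms: float,
) -> pd.DataFrame:
    """Mean diameter in consecutive half-open bins from t_start.

    Bins with no non-missing grid points get a NaN mean; a trailing
    partial bin is kept and flagged.  Short fixed-width bins (e.g.
    100 ms) turn the smoothed signal into a time series suitable for
    multilevel statistics.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be > 0")
    bin_s = bin_ms / 1000.0
    n_bins = int(np.ceil((t_end - t_start) / bin_s - 1e-9))
    rows = []
    for k in range(n_bins):
        b0 = t_start + k * bin_s
        b1 = min(b0 + bin_s, t_end)
        vals, _ = _window_values(signal, b0, b1)
        data = vals[~np.isnan(vals)]
        rows.append(
            {
                "bin_index": k,
                "bin_t_center_s": 0.5 * (b0 + b1),
                "mean_mm": float(data.mean()) if data.size else np.nan,
                "n_points": int(data.size),
                "partial": bool(b0 + bin_s > t_end + 1e-12),
            }
        )
    return pd.DataFrame(
        rows, columns=["bin_index", "bin_t_center_s", "mean_mm", "n_points", "partial"]
    )


def bin_segments(
    signal: SmoothSignal, segments: SegmentTable, bin_ms: float
) -> pd.DataFrame:
    """Long-format binned time courses for every segment."""
    frames = []
    for i in range(len(segments)):
        df = bin_timecourse(signal, segments.t_start[i], segments.t_end[i], bin_ms)
        df.insert(0, "segment_id", int(segments.segment_id[i]))
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["segment_id", "bin_index", "bin_t_center_s", "mean_mm", "n_points", "partial"]
        )
    return pd.concat(frames, ignore_index=True)


def pair_baselines(
    metrics: pd.DataFrame,
    pairing: dict[str, str],
) -> pd.DataFrame:
    """Match each response segment with its baseline segment's mean.

    ``pairing`` maps baseline label → response label.  Grouping uses a
    ``trial_id`` column when present; otherwise the nearest preceding
    baseline (by segment_id order) is used.  No correction is applied —
    the paired table lets the user subtract or divide as they prefer.
    """
    response_to_baseline = {resp: base for base, resp in pairing.items()}
    out_rows = []
    has_trial = "trial_id" in metrics.columns
    for _, row in metrics.iterrows():
        if row["label"] not in response_to_baseline:
            continue
        base_label = response_to_baseline[row["label"]]
        candidates = metrics[metrics["label"] == base_label]
        if has_trial:
            candidates = candidates[candidates["trial_id"] == row["trial_id"]]
        else:
            candidates = candidates[candidates["segment_id"] < row["segment_id"]]
        rec = row.to_dict()
        if len(candidates):
            base = candidates.iloc[-1]
            rec["baseline_segment_id"] = int(base["segment_id"])
            rec["baseline_mean_mm"] = float(base["mean_mm"])
            rec["baseline_missing"] = False
        else:
            rec["baseline_segment_id"] = -1
            rec["baseline_mean_mm"] = np.nan
            rec["baseline_missing"] = True
        out_rows.append(rec)
    cols = list(metrics.columns) + ["baseline_segment_id", "baseline_mean_mm", "baseline_missing"]
    return pd.DataFrame(out_rows, columns=cols)
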