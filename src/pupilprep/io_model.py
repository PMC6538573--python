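"""Standardized pupil-recording data model and tabular I/O.

A recording is reduced, on ingestion, to a timestamped pair of pupil
diameter series (left/right eye, millimetres, missing values allowed).
Clearly invalid samples — nonpositive diameters and samples flagged
invalid by the eyetracker — are removed here so the downstream filters
only ever see plausible candidates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("pupilprep")

STANDARD_COLUMNS = ("timestamp_s", "diameter_left_mm", "diameter_right_mm")
SEGMENT_COLUMNS = ("segment_id", "label", "t_start_s", "t_end_s")


class FormatError(ValueError):
    """Raised when an input file cannot be interpreted."""


class EmptyRecordingError(ValueError):
    """Raised when no samples survive ingestion."""


class InsufficientDataError(ValueError):
    """Raised when an operation needs more samples than are available."""


@dataclass
class FormatSpec:
    """Column mapping describing a vendor export.

    ``units`` is the unit of the timestamp column ('s' or 'ms'); internal
    timestamps are always seconds.  A validity column may apply per eye
    (``validity_left_col`` / ``validity_right_col``) or to the whole row
    (``validity_col``); a sample is invalid when its validity value is in
    ``invalid_values``.
    """

    timestamp_col: str = "timestamp_s"
    left_col: str | None = "diameter_left_mm"
    right_col: str | None = "diameter_right_mm"
    units: str = "s"
    validity_col: str | None = None
    validity_left_col: str | None = None
    validity_right_col: str | None = None
    invalid_values: Sequence[float] = (0, -1)

    def __post_init__(self) -> None:
        if self.units not in ("s", "ms"):
            raise ValueError(f"units must be 's' or 'ms', got {self.units!r}")
        if self.left_col is None and self.right_col is None:
            raise ValueError("at least one eye column must be mapped")


@dataclass
class RawRecording:
    """Nonuniformly sampled left/right pupil diameter series.

    Invariants: timestamps strictly increasing; every non-missing diameter
    finite and > 0; at least one eye carries data. Missing samples are NaN.
    """

    timestamps: np.ndarray
    left_mm: np.ndarray
    right_mm: np.ndarray
    source_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.left_mm = np.asarray(self.left_mm, dtype=float)
        self.right_mm = np.asarray(self.right_mm, dtype=float)
        n = self.timestamps.size
        if n == 0:
            raise EmptyRecordingError("recording has no samples")
        if self.left_mm.size != n or self.right_mm.size != n:
            raise ValueError("eye series must align with timestamps")
        if not np.all(np.isfinite(self.timestamps)):
            raise ValueError("timestamps must be finite")
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        for name, d in (("left", self.left_mm), ("right", self.right_mm)):
            present = ~np.isnan(d)
            if np.any(~np.isfinite(d[present])) or np.any(d[present] <= 0):
                raise ValueError(f"{name} diameters must be finite and > 0")
        if np.all(np.isnan(self.left_mm)) and np.all(np.isnan(self.right_mm)):
            raise EmptyRecordingError("no eye carries any data")

    @property
    def n_samples(self) -> int:
        return self.timestamps.size

    @property
    def eyes(self) -> tuple[str, ...]:
        out = []
        if not np.all(np.isnan(self.left_mm)):
            out.append("left")
        if not np.all(np.isnan(self.right_mm)):
            out.append("right")
        return tuple(out)

    def eye(self, which: str) -> np.ndarray:
        if which == "left":
            return self.left_mm
        if which == "right":
            return self.right_mm
        raise KeyError(which)


@dataclass
class SegmentTable:
    """Labeled time windows used to section the processed signal.

    Overlapping windows are allowed (a baseline may sit inside a trial);
    ``trial_id`` optionally groups baseline/response segments of one trial.
    """

    segment_id: np.ndarray
    label: np.ndarray
    t_start: np.ndarray
    t_end: np.ndarray
    trial_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.segment_id = np.asarray(self.segment_id, dtype=int)
        self.label = np.asarray(self.label, dtype=object)
        self.t_start = np.asarray(self.t_start, dtype=float)
        self.t_end = np.asarray(self.t_end, dtype=float)
        if self.trial_id is not None:
            self.trial_id = np.asarray(self.trial_id)
        n = self.segment_id.size
        for arr in (self.label, self.t_start, self.t_end):
            if arr.size != n:
                raise ValueError("segment table columns must align")
        if np.unique(self.segment_id).size != n:
            raise ValueError("segment_id values must be unique")
        if np.any(self.t_start >= self.t_end):
            bad = self.segment_id[self.t_start >= self.t_end]
            raise ValueError(f"t_start must be < t_end (segments {bad.tolist()})")

    def __len__(self) -> int:
        return self.segment_id.size

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "segment_id": self.segment_id,
                "label": self.label,
                "t_start_s": self.t_start,
                "t_end_s": self.t_end,
            }
        )
        if self.trial_id is not None:
            df["trial_id"] = self.trial_id
        return df


class ValidityMask:
    """Per-sample, per-stage record of which filter rejected what.

    Each layer is a boolean array aligned 1:1 with one eye's samples; True
    means the sample survives that stage. The combined mask is the logical
    AND of all layers. The base layer ``present`` marks samples that carry
    data at all (non-missing on ingestion).
    """

    def __init__(self, n_samples: int, present: np.ndarray | None = None):
        self.n_samples = int(n_samples)
        self.layers: dict[str, np.ndarray] = {}
        if present is None:
            present = np.ones(self.n_samples, dtype=bool)
        self.add_layer("present", present)

    def add_layer(self, name: str, mask: np.ndarray) -> None:
        mask = np.asarray(mask, dtype=bool)
        if mask.size != self.n_samples:
            raise ValueError(f"layer {name!r} does not align with samples")
        self.layers[name] = mask.copy()

    @property
    def combined(self) -> np.ndarray:
        out = np.ones(self.n_samples, dtype=bool)
        for mask in self.layers.values():
            out &= mask
        return out

    def rejected_by(self, name: str) -> np.ndarray:
        """Samples valid through every layer before ``name`` but not ``name``."""
        upstream = np.ones(self.n_samples, dtype=bool)
        for key, mask in self.layers.items():
            if key == name:
                return upstream & ~mask
            upstream &= mask
        raise KeyError(name)


def _apply_validity(
    d: np.ndarray, validity: np.ndarray | None, invalid_values: Sequence[float]
) -> tuple[np.ndarray, int]:
    """NaN-out samples whose validity value is a configured sentinel."""
    if validity is None:
        return d, 0
    bad = np.isin(validity, np.asarray(list(invalid_values), dtype=float))
    bad &= ~np.isnan(d)
    d = d.copy()
    d[bad] = np.nan
    return d, int(bad.sum())


def load_raw(path, format_spec: FormatSpec | Mapping | None = None) -> RawRecording:
    """Read a tabular eyetracker export into a :class:`RawRecording`.

    Nonpositive diameters and samples marked invalid by the tracker are
    dropped (set missing); rows left with no data at all are removed.
    Timestamps are converted to seconds, sorted, and exact duplicates
    collapsed (first occurrence wins) so downstream dilation speeds never
    divide by a zero time step.
    """
    if format_spec is None:
        format_spec = FormatSpec()
    elif isinstance(format_spec, Mapping):
        format_spec = FormatSpec(**format_spec)
    spec = format_spec

    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as e:
        raise FormatError(f"cannot parse {path}: {e}") from e

    needed = [spec.timestamp_col] + [
        c
        for c in (
            spec.left_col,
            spec.right_col,
            spec.validity_col,
            spec.validity_left_col,
            spec.validity_right_col,
        )
        if c is not None
    ]
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise FormatError(f"missing columns in {path}: {missing_cols}")

    t = pd.to_numeric(df[spec.timestamp_col], errors="coerce").to_numpy(dtype=float)
    if np.any(np.isnan(t)):
        raise FormatError(f"non-numeric timestamps in {path}")
    if spec.units == "ms":
        t = t / 1000.0

    def eye_series(col: str | None) -> np.ndarray:
        if col is None:
            return np.full(t.size, np.nan)
        return pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)

    left = eye_series(spec.left_col)
    right = eye_series(spec.right_col)

    counts = {"input_rows": int(t.size)}

    # Tracker-flagged invalid samples (per-row or per-eye encodings).
    row_validity = (
        pd.to_numeric(df[spec.validity_col], errors="coerce").to_numpy(dtype=float)
        if spec.validity_col
        else None
    )
    left, n_inv_l = _apply_validity(
        left,
        row_validity
        if row_validity is not None
        else (
            pd.to_numeric(df[spec.validity_left_col], errors="coerce").to_numpy(float)
            if spec.validity_left_col
            else None
        ),
        spec.invalid_values,
    )
    right, n_inv_r = _apply_validity(
        right,
        row_validity
        if row_validity is not None
        else (
            pd.to_numeric(df[spec.validity_right_col], errors="coerce").to_numpy(float)
            if spec.validity_right_col
            else None
        ),
        spec.invalid_values,
    )
    counts["tracker_invalid_samples"] = n_inv_l + n_inv_r

    # Nonpositive (or non-finite) diameters carry no information.
    n_nonpos = 0
    for d in (left, right):
        bad = ~np.isnan(d) & ((d <= 0) | ~np.isfinite(d))
        n_nonpos += int(bad.sum())
        d[bad] = np.nan
    counts["nonpositive_samples"] = n_nonpos

    order = np.argsort(t, kind="stable")
    t, left, right = t[order], left[order], right[order]

    keep = np.ones(t.size, dtype=bool)
    if t.size > 1:
        keep[1:] = np.diff(t) > 0
    counts["duplicate_timestamp_rows"] = int((~keep).sum())
    t, left, right = t[keep], left[keep], right[keep]

    empty = np.isnan(left) & np.isnan(right)
    counts["all_missing_rows_dropped"] = int(empty.sum())
    t, left, right = t[~empty], left[~empty], right[~empty]

    counts["retained_rows"] = int(t.size)
    logger.info(
        "load_raw(%s): %d rows in, %d retained (%d invalid-flagged samples, "
        "%d nonpositive samples, %d duplicate-timestamp rows, %d empty rows)",
        path,
        counts["input_rows"],
        counts["retained_rows"],
        counts["tracker_invalid_samples"],
        counts["nonpositive_samples"],
        counts["duplicate_timestamp_rows"],
        counts["all_missing_rows_dropped"],
    )
    if t.size == 0:
        raise EmptyRecordingError(f"no samples survive ingestion of {path}")

    return RawRecording(
        timestamps=t,
        left_mm=left,
        right_mm=right,
        source_meta={"path": str(path), "ingestion_counts": counts},
    )


def write_standard(rec: RawRecording, path, header_comment: str | None = None) -> None:
    """Write the standard raw CSV (timestamp_s, diameter_left_mm, diameter_right_mm).

    Missing diameters become empty cells; timestamps are written at full
    float precision so load_raw ∘ write_standard is the identity.
    """
    df = pd.DataFrame(
        {
            "timestamp_s": rec.timestamps,
            "diameter_left_mm": rec.left_mm,
            "diameter_right_mm": rec.right_mm,
        }
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        # pandas' default float repr is the shortest round-trip form, so
        # written values parse back bit-identically
        df.to_csv(fh, index=False, na_rep="")


def load_segments(path) -> SegmentTable:
    """Read a segment table CSV (segment_id, label, t_start_s, t_end_s[, trial_id])."""
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as e:
        raise FormatError(f"cannot parse {path}: {e}") from e
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"segment file {path} missing columns: {missing}")
    return SegmentTable(
        segment_id=df["segment_id"].to_numpy(),
        label=df["label"].to_numpy(dtype=object),
        t_start=df["t_start_s"].to_numpy(dtype=float),
        t_end=df["t_end_s"].to_numpy(dtype=float),
        trial_id=df["trial_id"].to_numpy() if "trial_id" in df.columns else None,
    )
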