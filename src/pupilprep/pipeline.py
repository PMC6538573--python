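"""End-to-end pipeline: standardize → filter → fuse/smooth → section.

Ties the library stages together behind one call, writing every
intermediate product (standardized raw data, filter report, processed
signals, segment tables) plus a run log and diagnostic figures, so the
fitness of the data and the filter settings can be reviewed visually.
"""
from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .filtering import run_filter_pipeline
from .io_model import RawRecording, load_raw, load_segments, write_standard
from .processing import SmoothSignal, combine_eyes, process_series
from .segmentation import bin_segments, pair_baselines, summarize_segments

logger = logging.getLogger("pupilprep")

STAGE_COLORS = {
    "range": "tab:red",
    "speed": "tab:orange",
    "gap_edge": "tab:purple",
    "deviation": "tab:brown",
    "sparsity": "tab:pink",
}


def _csv_header(config: PipelineConfig) -> str:
    return f"pupilprep v{__version__} config_hash={config.config_hash()}"


def _write_csv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# {_csv_header(config)}\n")
        df.to_csv(fh, index=False, na_rep="")


def process_recording(
    rec: RawRecording, masks: dict, config: PipelineConfig
) -> dict[str, SmoothSignal]:
    """Produce smoothed per-eye signals and, when binocular, the fused mean."""
    ps = config.processing
    signals: dict[str, SmoothSignal] = {}
    valid = {}
    for eye in rec.eyes:
        m = masks[eye].combined
        valid[eye] = (rec.timestamps[m], rec.eye(eye)[m])
        if m.sum() >= 2:
            signals[eye] = process_series(*valid[eye], ps, source=eye)
    if len(valid) == 2:
        fused = combine_eyes(
            valid["left"][0], valid["left"][1], valid["right"][0], valid["right"][1]
        )
        signals["mean"] = process_series(fused.t, fused.d, ps, source="mean")
    elif len(valid) == 1:
        # monocular recording: the "mean" signal is the single eye's
        ((eye, (tv, dv)),) = valid.items()
        if tv.size >= 2:
            signals["mean"] = process_series(tv, dv, ps, source="mean")
    return signals


def run_pipeline(
    raw_path,
    segments_path,
    config: PipelineConfig,
    out_dir=None,
    seed: int | None = None,
) -> Path:
    """Run all four preprocessing steps and write every output product.

    Outputs in ``out_dir``: standardized_raw.csv, filter_report.json,
    processed_<source>.csv per signal, segment_metrics.csv,
    binned_timecourse.csv, paired_baselines.csv, run_log.txt, and (unless
    disabled) diagnostic figures under plots/.
    """
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    rec = load_raw(raw_path, config.io)
    segments = load_segments(segments_path)
    write_standard(rec, out / "standardized_raw.csv", header_comment=_csv_header(config))

    masks, reports = run_filter_pipeline(rec, config.filter)
    with open(out / "filter_report.json", "w", encoding="utf-8") as fh:
        json.dump(
            {eye: rep.to_dict() for eye, rep in reports.items()}, fh, indent=2
        )

    signals = process_recording(rec, masks, config)
    for source, sig in signals.items():
        df = pd.DataFrame(
            {
                "timestamp_s": sig.t,
                "diameter_mm": sig.d,
                "source": sig.source,
                "interpolated_over_gap": sig.over_gap.astype(int),
            }
        )
        _write_csv(df, out / f"processed_{source}.csv", config)

    max_missing = config.segmentation.require_max_missing_pct()
    main_signal = signals["mean"]
    metrics = summarize_segments(main_signal, segments, max_missing)
    _write_csv(metrics, out / "segment_metrics.csv", config)

    binned = bin_segments(main_signal, segments, config.segmentation.bin_ms)
    _write_csv(binned, out / "binned_timecourse.csv", config)

    paired = pair_baselines(metrics, config.segmentation.pairing)
    _write_csv(paired, out / "paired_baselines.csv", config)

    with open(out / "run_log.txt", "w", encoding="utf-8") as fh:
        fh.write(f"pupilprep v{__version__}\n")
        fh.write(f"python {platform.python_version()} numpy {np.__version__}\n")
        fh.write(f"seed: {seed}\n")
        fh.write(f"config_hash: {config.config_hash()}\n")
        fh.write("effective settings:\n")
        fh.write(json.dumps(config.to_dict(), indent=2, default=str))
        fh.write("\ningestion: ")
        fh.write(json.dumps(rec.source_meta.get("ingestion_counts", {})))
        fh.write("\n")

    if config.plots:
        try:
            plot_steps(rec, masks, signals, out / "plots")
        except Exception:  # plotting must never sink the pipeline outputs
            logger.exception("diagnostic plotting failed; pipeline outputs unaffected")
    return out


def plot_steps(rec: RawRecording, masks: dict, signals: dict, out_dir) -> list[Path]:
    """Diagnostic figures: per-stage rejections, and raw-vs-smooth overlay."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for eye in rec.eyes:
        fig, ax = plt.subplots(figsize=(12, 4))
        d = rec.eye(eye)
        vm = masks[eye]
        ax.plot(rec.timestamps[vm.combined], d[vm.combined], ".", ms=2,
                color="tab:gray", label="valid")
        stage_names = [k for k in vm.layers if k not in ("present",)]
        for name in stage_names:
            rej = vm.rejected_by(name)
            if not rej.any():
                continue
            base = name.split("_pass_")[0] if "_pass_" in name else name
            color = STAGE_COLORS.get("deviation" if base == "deviation" else base, "k")
            ax.plot(rec.timestamps[rej], d[rej], "x", ms=4, color=color, label=name)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("pupil diameter (mm)")
        ax.set_title(f"{eye} eye: raw samples and per-stage rejections")
        ax.legend(loc="upper right", fontsize=7)
        path = out / f"filter_stages_{eye}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)

    fig, ax = plt.subplots(figsize=(12, 4))
    any_data = False
    for eye, color in (("left", "tab:red"), ("right", "tab:blue")):
        if eye in masks:
            m = masks[eye].combined
            if m.any():
                any_data = True
                ax.plot(rec.timestamps[m], rec.eye(eye)[m], ".", ms=2, color=color,
                        alpha=0.5, label=f"{eye} valid raw")
    if "mean" in signals:
        sig = signals["mean"]
        ax.plot(sig.t, sig.d, "-", color="tab:green", lw=1.5, label="smoothed mean")
        any_data = True
    if not any_data:
        ax.text(0.5, 0.5, "no valid samples — check data and filter settings",
                ha="center", va="center", transform=ax.transAxes)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("pupil diameter (mm)")
    ax.set_title("valid raw samples and smoothed mean pupil signal")
    ax.legend(loc="upper right", fontsize=8)
    path = out / "smooth_overlay.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    written.append(path)
    return written
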