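"""Seedable synthetic pupil recordings with a ground-truth artifact ledger.

The generator emulates what a video eyetracker actually delivers: a
smooth physiological pupil trace (a low-frequency sum of sinusoids
inside the feasible 1.5–9 mm diameter window) sampled at a nominal rate
with optional timestamp jitter, measurement noise, a slowly varying
left–right size offset, and the artifact taxonomy the filters target:

* **blinks** — missing-data gaps flanked by short ramped dips, the
  signature of progressive eyelid occlusion before/after a blink;
* **spikes** — isolated samples displaced by a large amplitude
  (momentary pupil-detection errors);
* **clusters** — short runs of consecutively displaced samples that
  defeat sample-to-sample speed tests;
* **islands** — brief runs of samples stranded inside longer gaps
  (glitch detections during closed eyes).

Every injected artifact is recorded in a ledger labeling each sample,
so filter sensitivity and false-rejection rates can be measured exactly.
It makes no attempt at mechanistic pupil physiology (no light-reflex
dynamics); it is a test harness, not a model of the eye.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .io_model import RawRecording

CLEAN = "clean"
SPIKE = "spike"
CLUSTER = "cluster"
ISLAND = "island"
BLINK_EDGE = "blink_edge"
BLINK_GAP = "blink_gap"  # missing samples, not present in the data
ISLAND_FLANK = "island_flank_gap"  # missing samples flanking an island

ARTIFACT_CLASSES = (SPIKE, CLUSTER, ISLAND, BLINK_EDGE)
MISSING_CLASSES = (BLINK_GAP, ISLAND_FLANK)


class GenerationError(ValueError):
    """Artifact specs cannot be placed without overlapping."""


@dataclass
class SyntheticScenario:
    """Study conditions for one synthetic recording.

    Defaults describe a realistic 60 s binocular recording at 250 Hz:
    ~4.7 mm baseline diameter with slow (≤ 0.3 Hz) fluctuations of a few
    tenths of a millimetre, 0.03 mm measurement noise, a 0.3 mm
    inter-eye size offset drifting slowly over the recording, ten blinks
    per minute, and a sprinkling of spike/cluster/island artifacts with
    amplitudes at least ten times the noise SD.
    """

    seed: int = 0
    duration_s: float = 60.0
    rate_hz: float = 250.0
    timestamp_jitter_pct: float = 5.0
    base_mm: float = 4.7
    sinusoids: tuple = ((0.5, 0.12), (0.25, 0.30))  # (amplitude_mm, freq_hz), ≤ 1 Hz
    noise_sd_mm: float = 0.03
    eye_offset_mm: float = 0.3
    eye_offset_drift_mm: float = 0.1
    blink_count: int = 10
    blink_gap_ms: float = 120.0
    blink_edge_dip_depth_mm: float = 1.0
    blink_edge_dip_ms: float = 12.0
    spike_count: int = 8
    spike_amplitude_mm: float = 1.0
    cluster_count: int = 3
    cluster_length: int = 5
    cluster_offset_mm: float = 0.6
    island_count: int = 2
    island_ms: float = 45.0
    island_flank_gap_ms: float = 60.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.rate_hz <= 0:
            raise ValueError("duration and rate must be positive")
        if not 0 <= self.timestamp_jitter_pct < 50:
            raise ValueError("timestamp_jitter_pct must be in [0, 50)")
        if not 1.5 <= self.base_mm <= 9.0:
            raise ValueError("base_mm must lie in the feasible 1.5-9 mm window")
        for amp, freq in self.sinusoids:
            if freq > 1.0:
                raise ValueError("sinusoid frequencies must be <= 1 Hz")
        if self.noise_sd_mm < 0:
            raise ValueError("noise_sd_mm must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sinusoids"] = [list(p) for p in self.sinusoids]
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticScenario":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        data = dict(data)
        if "sinusoids" in data:
            data["sinusoids"] = tuple(tuple(p) for p in data["sinusoids"])
        return cls(**data)


class TruthSignal:
    """The noiseless true mean-pupil trace, evaluable at any time."""

    def __init__(self, base_mm, sinusoids, phases):
        self.base_mm = float(base_mm)
        self.sinusoids = [(float(a), float(f)) for a, f in sinusoids]
        self.phases = np.asarray(phases, dtype=float)

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.base_mm)
        for (amp, freq), ph in zip(self.sinusoids, self.phases):
            out = out + amp * np.sin(2 * np.pi * freq * t + ph)
        return out

    @property
    def peak_to_peak(self) -> float:
        return 2.0 * sum(a for a, _ in self.sinusoids)


@dataclass
class GroundTruthLedger:
    """Per-sample labels and event list for every injected artifact."""

    labels: dict  # eye -> array of class strings aligned with samples
    events: list = field(default_factory=list)

    def artifact_mask(self, eye: str) -> np.ndarray:
        """Present samples whose value was corrupted by construction."""
        return np.isin(self.labels[eye], ARTIFACT_CLASSES)

    def clean_mask(self, eye: str) -> np.ndarray:
        return np.asarray(self.labels[eye]) == CLEAN


def _place_slots(rng, durations, duration_s, edge_margin_s=1.0, guard_s=0.35, max_tries=10_000):
    """Random non-overlapping start times for artifact events."""
    placed: list[tuple[float, float]] = []
    starts = []
    for dur in durations:
        ok = False
        for _ in range(max_tries):
            start = rng.uniform(edge_margin_s, duration_s - edge_margin_s - dur)
            lo, hi = start - guard_s, start + dur + guard_s
            if all(hi <= s or lo >= e for s, e in placed):
                placed.append((lo, hi))
                starts.append(start)
                ok = True
                break
        if not ok:
            raise GenerationError(
                f"cannot place an artifact of {dur:.3f}s without overlap; "
                f"reduce counts/durations (have {len(placed)} events in {duration_s}s)"
            )
    return starts


def generate(
    scenario: SyntheticScenario,
) -> tuple[RawRecording, GroundTruthLedger, TruthSignal]:
    """Render a scenario into a two-eye recording, ledger, and true signal.

    Identical scenario (including seed) → bit-identical output.  Blinks
    and the other artifacts are applied binocularly (both eyes at the
    same samples), as real blinks are.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)

    n = int(round(sc.duration_s * sc.rate_hz))
    step = 1.0 / sc.rate_hz
    t = step * np.arange(n)
    if sc.timestamp_jitter_pct > 0:
        jitter = rng.uniform(-1, 1, n) * (sc.timestamp_jitter_pct / 100.0) * step
        t = t + jitter  # |jitter| < step/2 keeps order strict

    phases = rng.uniform(0, 2 * np.pi, len(sc.sinusoids))
    truth = TruthSignal(sc.base_mm, sc.sinusoids, phases)
    true_mean = truth(t)

    offset_phase = rng.uniform(0, 2 * np.pi)
    offset = sc.eye_offset_mm + sc.eye_offset_drift_mm * np.sin(
        2 * np.pi * 0.03 * t + offset_phase
    )

    eyes = {
        "left": true_mean - offset / 2 + rng.normal(0, sc.noise_sd_mm, n),
        "right": true_mean + offset / 2 + rng.normal(0, sc.noise_sd_mm, n),
    }
    labels = np.full(n, CLEAN, dtype=object)
    events: list[dict] = []

    gap_s = sc.blink_gap_ms / 1000.0
    edge_s = sc.blink_edge_dip_ms / 1000.0
    island_s = sc.island_ms / 1000.0
    flank_s = sc.island_flank_gap_ms / 1000.0
    cluster_s = sc.cluster_length * step

    durations = (
        [gap_s + 2 * edge_s] * sc.blink_count
        + [step] * sc.spike_count
        + [cluster_s] * sc.cluster_count
        + [island_s + 2 * flank_s] * sc.island_count
    )
    starts = _place_slots(rng, durations, sc.duration_s)
    kinds = (
        ["blink"] * sc.blink_count
        + ["spike"] * sc.spike_count
        + ["cluster"] * sc.cluster_count
        + ["island"] * sc.island_count
    )

    def idx_in(lo, hi):
        return np.flatnonzero((t >= lo) & (t < hi))

    for kind, start in zip(kinds, starts):
        if kind == "blink":
            pre = idx_in(start, start + edge_s)
            gap = idx_in(start + edge_s, start + edge_s + gap_s)
            post = idx_in(start + edge_s + gap_s, start + 2 * edge_s + gap_s)
            # ramp toward the gap: deepest dip at the gap border
            for eye in eyes:
                if pre.size:
                    ramp = np.linspace(1.0 / pre.size, 1.0, pre.size)
                    eyes[eye][pre] -= sc.blink_edge_dip_depth_mm * ramp
                eyes[eye][gap] = np.nan
                if post.size:
                    ramp = np.linspace(1.0, 1.0 / post.size, post.size)
                    eyes[eye][post] -= sc.blink_edge_dip_depth_mm * ramp
            labels[pre] = BLINK_EDGE
            labels[gap] = BLINK_GAP
            labels[post] = BLINK_EDGE
            events.append(
                {"class": "blink", "start_s": start, "end_s": start + 2 * edge_s + gap_s,
                 "indices": np.concatenate([pre, gap, post]).tolist()}
            )
        elif kind == "spike":
            cand = idx_in(start, start + step)
            if cand.size == 0:
                cand = np.array([np.searchsorted(t, start) % n])
            i = int(cand[0])
            sign = rng.choice([-1.0, 1.0])
            for eye in eyes:
                eyes[eye][i] += sign * sc.spike_amplitude_mm
            labels[i] = SPIKE
            events.append({"class": "spike", "start_s": float(t[i]), "end_s": float(t[i]), "indices": [i]})
        elif kind == "cluster":
            i0 = int(np.searchsorted(t, start))
            sel = np.arange(i0, min(i0 + sc.cluster_length, n))
            sign = rng.choice([-1.0, 1.0])
            for eye in eyes:
                eyes[eye][sel] += sign * sc.cluster_offset_mm
            labels[sel] = CLUSTER
            events.append({"class": "cluster", "start_s": float(t[sel[0]]), "end_s": float(t[sel[-1]]), "indices": sel.tolist()})
        else:  # island
            flank1 = idx_in(start, start + flank_s)
            isle = idx_in(start + flank_s, start + flank_s + island_s)
            flank2 = idx_in(start + flank_s + island_s, start + 2 * flank_s + island_s)
            for eye in eyes:
                eyes[eye][flank1] = np.nan
                eyes[eye][flank2] = np.nan
            labels[flank1] = ISLAND_FLANK
            labels[flank2] = ISLAND_FLANK
            labels[isle] = ISLAND
            events.append(
                {"class": "island", "start_s": start, "end_s": start + 2 * flank_s + island_s,
                 "indices": np.concatenate([flank1, isle, flank2]).tolist()}
            )

    # clip to physical positivity (dips from an already small pupil)
    for eye in eyes:
        d = eyes[eye]
        d[~np.isnan(d) & (d <= 0.1)] = 0.1

    rec = RawRecording(
        timestamps=t,
        left_mm=eyes["left"],
        right_mm=eyes["right"],
        source_meta={"synthetic_scenario": sc.to_dict()},
    )
    ledger = GroundTruthLedger(
        labels={"left": labels.copy(), "right": labels.copy()}, events=events
    )
    return rec, ledger, truth
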