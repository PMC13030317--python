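"""Recording containers, CSV/JSON round-trip, tagging, calibration profiles,
two-stage normalization and sliding-window segmentation.

Conventions: sample indices are 0-based; event intervals are half-open
``[start, end)`` in samples.  Normalization is affine per channel,
``x' = (x - neutral) / (mvic - neutral)``: the resting tone maps to ~0 and a
maximal voluntary contraction to ~1, with no clipping (spontaneous activity
may legitimately exceed the calibration maximum).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .types import CHANNELS, LABEL_NAMES, N_CHANNELS

#: Minimum usable dynamic range (mvic - neutral) per channel, normalized units.
EPS_RANGE = 1e-6


@dataclass
class Event:
    """Half-open labeled interval [start, end) in sample indices."""

    label: str
    start: int
    end: int

    def to_seconds(self, sample_rate: float) -> dict:
        return {
            "label": self.label,
            "start_s": self.start / sample_rate,
            "end_s": self.end / sample_rate,
        }


@dataclass
class MultiChannelRecording:
    """A 7-channel amplitude time-series with sample rate and tagged events."""

    participant: str
    samples: np.ndarray  # (n_samples, 7) float64
    sample_rate: float
    events: list[Event] = field(default_factory=list)
    normalized: bool = False
    scene: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or self.samples.shape[1] != N_CHANNELS:
            raise ValueError(f"samples must be (n, {N_CHANNELS}), got {self.samples.shape}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        for ev in self.events:
            self._check_event(ev)

    def _check_event(self, ev: Event) -> None:
        if not (0 <= ev.start <= ev.end <= self.n_samples):
            raise ValueError(
                f"event {ev.label!r} [{ev.start}, {ev.end}) outside [0, {self.n_samples}]"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class CalibrationProfile:
    """Per-participant, per-channel neutral resting tone and MVIC amplitude."""

    participant: str
    neutral_baseline: np.ndarray  # (7,)
    mvic: np.ndarray  # (7,)

    def __post_init__(self) -> None:
        self.neutral_baseline = np.asarray(self.neutral_baseline, dtype=float)
        self.mvic = np.asarray(self.mvic, dtype=float)
        if self.neutral_baseline.shape != (N_CHANNELS,) or self.mvic.shape != (N_CHANNELS,):
            raise ValueError("profile arrays must have shape (7,)")
        if np.any(self.mvic - self.neutral_baseline <= EPS_RANGE):
            bad = [CHANNELS[i] for i in np.flatnonzero(self.mvic - self.neutral_baseline <= EPS_RANGE)]
            raise ValueError(f"mvic must exceed neutral baseline on every channel; bad: {bad}")


@dataclass(frozen=True)
class WindowingParams:
    """Window length and stride in samples; the default stride equals the
    window length (zero overlap)."""

    w: int = 1000
    s: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "s", self.w if self.s is None else self.s)
        if self.w < 1 or self.s < 1:
            raise ValueError("window length and stride must be >= 1")


@dataclass
class LabeledWindow:
    """A fixed-length (w x 7) window; ``label`` is set only for calibration
    windows whose samples all share one expression label."""

    data: np.ndarray
    label: str | None
    participant: str
    scene: str | None
    start: int


def window_count(T: int, w: int, s: int) -> int:
    """Number of complete windows in a segment of T samples."""
    return (T - w) // s + 1 if T >= w else 0


# ---------------------------------------------------------------------------
# CSV/JSON round-trip


def write_recording(rec: MultiChannelRecording, path_csv: str | Path, path_json: str | Path) -> None:
    """Write samples as CSV (time_s + 7 channel columns, fixed order) and a
    JSON sidecar with participant, scene, sample rate and events in seconds."""
    path_csv, path_json = Path(path_csv), Path(path_json)
    t = np.arange(rec.n_samples) / rec.sample_rate
    df = pd.DataFrame({"time_s": t})
    for i, ch in enumerate(CHANNELS):
        df[ch] = rec.samples[:, i]
    df.to_csv(path_csv, index=False, float_format="%.17g")
    sidecar = {
        "participant_id": rec.participant,
        "scene": rec.scene,
        "sample_rate_hz": rec.sample_rate,
        "normalized": rec.normalized,
        "events": [ev.to_seconds(rec.sample_rate) for ev in rec.events],
    }
    path_json.write_text(json.dumps(sidecar, indent=1))


def read_recording(path_csv: str | Path, path_json: str | Path) -> MultiChannelRecording:
    """Read a recording back; raises on missing channel columns or events
    extending beyond the sample range."""
    df = pd.read_csv(path_csv)
    missing = [ch for ch in CHANNELS if ch not in df.columns]
    if missing:
        raise ValueError(f"CSV {path_csv} missing channel column(s): {missing}")
    samples = df[list(CHANNELS)].to_numpy(dtype=np.float64)
    meta = json.loads(Path(path_json).read_text())
    fs = float(meta["sample_rate_hz"])
    events = [
        Event(ev["label"], int(round(ev["start_s"] * fs)), int(round(ev["end_s"] * fs)))
        for ev in meta.get("events", [])
    ]
    return MultiChannelRecording(
        participant=str(meta["participant_id"]),
        samples=samples,
        sample_rate=fs,
        events=events,
        normalized=bool(meta.get("normalized", False)),
        scene=meta.get("scene"),
    )


# ---------------------------------------------------------------------------
# Tagging


def tag_recording(rec: MultiChannelRecording, events: list[Event]) -> MultiChannelRecording:
    """Attach events after validating bounds and pairwise non-overlap.
    Samples outside every event remain untagged and yield no windows."""
    events = sorted(events, key=lambda e: e.start)
    out = replace(rec, events=events)
    for a, b in zip(events, events[1:]):
        if b.start < a.end:
            raise ValueError(
                f"overlapping events: {a.label!r} [{a.start},{a.end}) and "
                f"{b.label!r} [{b.start},{b.end})"
            )
    return out


def sample_labels(rec: MultiChannelRecording) -> np.ndarray:
    """Per-sample label resolution: object array of label strings, with None
    for untagged samples."""
    lab = np.full(rec.n_samples, None, dtype=object)
    for ev in rec.events:
        lab[ev.start : ev.end] = ev.label
    return lab


# ---------------------------------------------------------------------------
# Calibration profile


def compute_calibration_profile(rec: MultiChannelRecording) -> CalibrationProfile:
    """Estimate the per-channel resting tone (median over neutral blocks) and
    MVIC (95th percentile over all maximal-expression blocks pooled)."""
    neutral = [ev for ev in rec.events if ev.label == "neutral"]
    maximal = [ev for ev in rec.events if ev.label in LABEL_NAMES and ev.label != "neutral"]
    if not neutral:
        raise ValueError("calibration recording contains no neutral block")
    if not maximal:
        raise ValueError("calibration recording contains no maximal-expression block")
    neutral_samples = np.concatenate([rec.samples[ev.start : ev.end] for ev in neutral])
    maximal_samples = np.concatenate([rec.samples[ev.start : ev.end] for ev in maximal])
    baseline = np.median(neutral_samples, axis=0)
    mvic = np.percentile(maximal_samples, 95, axis=0)
    return CalibrationProfile(rec.participant, baseline, mvic)


# ---------------------------------------------------------------------------
# Normalization


def normalize(rec: MultiChannelRecording, profile: CalibrationProfile) -> MultiChannelRecording:
    """Two-stage normalization: neutral correction then MVIC scaling, i.e.
    the per-channel affine map (x - neutral) / (mvic - neutral).  Values
    outside [0, 1] are kept."""
    if rec.normalized:
        raise ValueError("recording is already normalized")
    if rec.participant != profile.participant:
        raise ValueError(
            f"participant mismatch: recording {rec.participant!r} vs profile {profile.participant!r}"
        )
    rng = profile.mvic - profile.neutral_baseline
    data = (rec.samples - profile.neutral_baseline) / rng
    return replace(rec, samples=data, normalized=True)


def denormalize(rec: MultiChannelRecording, profile: CalibrationProfile) -> MultiChannelRecording:
    """Inverse of :func:`normalize`."""
    if not rec.normalized:
        raise ValueError("recording is not normalized")
    if rec.participant != profile.participant:
        raise ValueError("participant mismatch")
    rng = profile.mvic - profile.neutral_baseline
    data = rec.samples * rng + profile.neutral_baseline
    return replace(rec, samples=data, normalized=False)


# ---------------------------------------------------------------------------
# Windowing


def segment_windows(
    rec: MultiChannelRecording,
    params: WindowingParams,
    *,
    require_normalized: bool = True,
) -> list[LabeledWindow]:
    """Cut each tagged contiguous segment into complete windows of length w
    with stride s; partial trailing windows are discarded.  A window inherits
    the segment's label when it is an expression label (calibration data);
    scene-tagged segments yield unlabeled windows."""
    if require_normalized and not rec.normalized:
        raise ValueError("recording must be normalized before windowing")
    w, s = params.w, params.s
    out: list[LabeledWindow] = []
    for ev in rec.events:
        T = ev.end - ev.start
        label = ev.label if ev.label in LABEL_NAMES else None
        for k in range(window_count(T, w, s)):
            start = ev.start + k * s
            out.append(
                LabeledWindow(
                    data=rec.samples[start : start + w],
                    label=label,
                    participant=rec.participant,
                    scene=rec.scene,
                    start=start,
                )
            )
    return out
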