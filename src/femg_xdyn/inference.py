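"""Apply the final classifier to continuous scene recordings and summarize
predicted expression sequences at the scene level.

The recording is segmented with the same windowing procedure as training
(default zero-overlap stride); each window's argmax becomes one label of the
continuous expression sequence.  Scene summaries report per-class occupancy
proportions, the non-neutral proportion, and each participant's change
relative to their own baseline scene (delta values).  No temporal smoothing
is applied by default: downstream features depend on the raw transition
structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_preprocess import MultiChannelRecording, WindowingParams, segment_windows
from .model import ExpressionClassifier
from .types import LABEL_NAMES, LABEL_TO_ID, N_CLASSES


@dataclass
class ExpressionSequence:
    """Chronological predicted labels, one per retained window."""

    participant: str
    scene: str
    labels: list[str]
    window_times: list[float]  # window start times (s)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class SceneSummary:
    """Per participant x scene occupancy proportions and baseline deltas."""

    participant: str
    scene: str
    proportions: np.ndarray  # (4,) in fixed class order
    non_neutral: float
    delta_proportions: np.ndarray | None = None
    delta_non_neutral: float | None = None


def majority_filter(labels: list[str], k: int = 3) -> list[str]:
    """Optional (off by default) sliding majority smoothing of a label
    sequence; ties keep the current label."""
    if k < 2 or len(labels) < k:
        return list(labels)
    half = k // 2
    out = []
    for i, lbl in enumerate(labels):
        window = labels[max(0, i - half) : i + half + 1]
        counts = {c: window.count(c) for c in set(window)}
        best = max(counts.values())
        winners = [c for c, n in counts.items() if n == best]
        out.append(lbl if lbl in winners else min(winners, key=LABEL_TO_ID.get))
    return out


def predict_sequence(
    model: ExpressionClassifier,
    rec: MultiChannelRecording,
    params: WindowingParams | None = None,
    smooth: int = 0,
) -> ExpressionSequence:
    """Predict the continuous expression sequence of a normalized scene
    recording.  Partial trailing windows are discarded, as in training."""
    if not rec.normalized:
        raise ValueError("recording must be normalized before inference")
    params = params or WindowingParams(model.window_len)
    if params.w != model.window_len:
        raise ValueError(f"window length {params.w} does not match training ({model.window_len})")
    windows = segment_windows(rec, params)
    if not windows:
        warnings.warn(
            f"recording {rec.participant}/{rec.scene} shorter than one window; empty sequence"
        )
        return ExpressionSequence(rec.participant, rec.scene or "", [], [])
    X = np.stack([w.data for w in windows])
    ids = model.predict(X)
    labels = [LABEL_NAMES[i] for i in ids]
    if smooth:
        labels = majority_filter(labels, smooth)
    times = [w.start / rec.sample_rate for w in windows]
    return ExpressionSequence(rec.participant, rec.scene or "", labels, times)


def class_proportions(seq: ExpressionSequence | list[str]) -> np.ndarray:
    """Occupancy proportion of each class, fixed order; sums to 1."""
    labels = seq.labels if isinstance(seq, ExpressionSequence) else list(seq)
    if not labels:
        raise ValueError("empty sequence")
    ids = np.array([LABEL_TO_ID[lbl] for lbl in labels])
    return np.bincount(ids, minlength=N_CLASSES) / ids.size


def summarize_sequence(seq: ExpressionSequence) -> SceneSummary:
    p = class_proportions(seq)
    return SceneSummary(seq.participant, seq.scene, p, float(1.0 - p[0]))


def baseline_corrected(summaries: list[SceneSummary]) -> list[SceneSummary]:
    """Subtract each participant's own baseline-scene proportions.  The
    baseline scene's own deltas are exactly 0."""
    by_participant: dict[str, SceneSummary] = {
        s.participant: s for s in summaries if s.scene == "baseline"
    }
    out = []
    for s in summaries:
        base = by_participant.get(s.participant)
        if base is None:
            raise ValueError(f"missing baseline scene for participant {s.participant!r}")
        dp = s.proportions - base.proportions
        out.append(
            SceneSummary(
                s.participant,
                s.scene,
                s.proportions,
                s.non_neutral,
                delta_proportions=dp,
                delta_non_neutral=float(s.non_neutral - base.non_neutral),
            )
        )
    return out


def cohort_scene_table(summaries: list[SceneSummary]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format participant x scene table and scene-level aggregates
    (mean delta per class; median and IQR of the non-neutral delta)."""
    if not summaries:
        raise ValueError("no summaries")
    if summaries and summaries[0].delta_proportions is None:
        summaries = baseline_corrected(summaries)
    rows = []
    for s in summaries:
        row = {"participant": s.participant, "scene": s.scene, "non_neutral": s.non_neutral,
               "delta_non_neutral": s.delta_non_neutral}
        for c, name in enumerate(LABEL_NAMES):
            row[f"prop_{name}"] = s.proportions[c]
            row[f"delta_{name}"] = s.delta_proportions[c]
        rows.append(row)
    table = pd.DataFrame(rows)
    agg = table.groupby("scene").agg(
        **{f"mean_delta_{name}": (f"delta_{name}", "mean") for name in LABEL_NAMES},
        mean_delta_non_neutral=("delta_non_neutral", "mean"),
        median_delta_non_neutral=("delta_non_neutral", "median"),
        iqr_delta_non_neutral=("delta_non_neutral", lambda v: float(np.subtract(*np.percentile(v, [75, 25])))),
        n=("participant", "count"),
    ).reset_index()
    return table, agg
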