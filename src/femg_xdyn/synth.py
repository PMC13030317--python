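"""Seeded synthetic fEMG cohort generator.

Emulates the statistical structure the downstream pipeline assumes:

* per-participant physiology — a resting tone and an MVIC amplitude per
  channel, drawn once per participant;
* expression scripts — a two-state renewal process at window granularity:
  a neutral background interrupted by expression bursts whose onset rate and
  class mixture depend on the scene (suppressed expressiveness under
  cognitive demand, smile-dominated bursts under physical and dual demand,
  raised-eyebrow-enriched bursts under emotional demand);
* amplitude rendering — each burst drives the FACS-involved channels with a
  smooth raised-cosine (Hann) rise-and-fall envelope peaking at a fraction of
  that channel's dynamic range, plus Gaussian noise and rectification;
* calibration sessions — alternating blocks of held maximal expressions with
  neutral interleaves, driving involved channels to ~MVIC;
* NASA-TLX ratings — 8 subscales on a 0-10 scale from a linear mixed model
  with participant random intercepts, scene fixed effects and configurable
  planted feature effects.

Every output is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from .io_preprocess import CalibrationProfile, Event, MultiChannelRecording, write_recording
from .types import (
    COHORT_SCENES,
    LABEL_NAMES,
    N_CHANNELS,
    NON_NEUTRAL,
    SCENES,
    involved_channels,
)

#: Default per-step burst onset probability per scene (neutral background).
#: Ordered so non-neutral occupancy satisfies
#: cognitive < baseline ~ emotional < physical ~ dual.
DEFAULT_BURST_ONSET = {
    "baseline": 0.06,
    "emotional": 0.07,
    "cognitive": 0.02,
    "physical": 0.14,
    "dual": 0.15,
    "recovery": 0.06,
}

#: Default burst class mixture (smile, frown, raised_eyebrow) per scene.
DEFAULT_BURST_MIX = {
    "baseline": (0.50, 0.20, 0.30),
    "emotional": (0.30, 0.20, 0.50),
    "cognitive": (0.34, 0.33, 0.33),
    "physical": (0.80, 0.05, 0.15),
    "dual": (0.75, 0.10, 0.15),
    "recovery": (0.50, 0.20, 0.30),
}

DEFAULT_SUBSCALES = (
    "mental",
    "physical",
    "temporal",
    "performance",
    "effort",
    "frustration",
    "emotional",
    "overall",
)

#: Default scene shifts (rating units) added per subscale; absent scenes -> 0.
DEFAULT_SCENE_EFFECTS: dict[str, dict[str, float]] = {
    "mental": {"cognitive": 3.0, "dual": 3.0, "emotional": 1.0},
    "physical": {"physical": 3.0, "dual": 3.0, "cognitive": 0.5, "emotional": 0.5},
    "temporal": {"cognitive": 1.5, "dual": 2.0},
    "performance": {},
    "effort": {"physical": 2.0, "dual": 2.5, "cognitive": 1.5},
    "frustration": {"emotional": 1.5, "cognitive": 1.0},
    "emotional": {"emotional": 3.0},
    "overall": {"cognitive": 1.5, "physical": 1.5, "dual": 2.0, "emotional": 1.0},
}

#: Default planted association: higher smile occupancy -> lower perceived
#: physical demand (the qualitative pattern the statistics stage must
#: recover). Keys are (subscale, feature_name).
DEFAULT_PLANTED_BETAS: dict[tuple[str, str], float] = {("physical", "ratio_smile"): -1.0}


@dataclass
class SyntheticConfig:
    """Cohort generation parameters.

    Durations are seconds, amplitudes arbitrary device units. ``snr`` is the
    ratio of burst peak amplitude to noise standard deviation on a channel.
    """

    n_participants: int = 12
    sample_rate: float = 1000.0
    scene_duration: float = 120.0
    baseline_duration: float = 300.0
    window_duration: float = 1.0
    burst_onset_prob: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BURST_ONSET))
    burst_mix: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BURST_MIX)
    )
    burst_duration_range: tuple[int, int] = (2, 5)  # steps (windows)
    burst_peak_fraction: float = 0.7
    peak_jitter: float = 0.1
    snr: float = 20.0
    baseline_tone_range: tuple[float, float] = (0.05, 0.2)
    mvic_range: tuple[float, float] = (0.8, 1.5)
    crosstalk: float = 0.0
    calib_block_duration: float = 4.0
    calib_reps: int = 3
    subscales: tuple[str, ...] = DEFAULT_SUBSCALES
    tlx_intercept: float = 4.0
    scene_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SCENE_EFFECTS.items()}
    )
    planted_betas: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_BETAS)
    )
    random_intercept_sd: float = 1.0
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("sample_rate", "scene_duration", "baseline_duration", "window_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.snr <= 0:
            raise ValueError("snr must be > 0")
        for rng_name in ("baseline_tone_range", "mvic_range"):
            lo, hi = getattr(self, rng_name)
            if hi < lo:
                raise ValueError(f"{rng_name} is inverted: {(lo, hi)}")
        if self.mvic_range[0] <= self.baseline_tone_range[1]:
            raise ValueError("mvic_range must lie strictly above baseline_tone_range")
        lo, hi = self.burst_duration_range
        if lo < 1 or hi < lo:
            raise ValueError("burst_duration_range must satisfy 1 <= lo <= hi")
        if not 0 <= self.crosstalk < 1:
            raise ValueError("crosstalk must be in [0, 1)")


@dataclass
class ExpressionScript:
    """Ground-truth label sequence of one participant x scene at window
    granularity (one label per future analysis window)."""

    participant: str
    scene: str
    labels: list[str]
    window_duration: float

    @property
    def n_steps(self) -> int:
        return len(self.labels)


@dataclass
class Cohort:
    """A generated cohort bundle."""

    config: SyntheticConfig
    profiles: dict[str, CalibrationProfile]
    calibrations: dict[str, MultiChannelRecording]
    recordings: dict[tuple[str, str], MultiChannelRecording]
    scripts: dict[tuple[str, str], ExpressionScript]
    script_features: pd.DataFrame  # participant, scene + 81 feature columns
    ratings: pd.DataFrame  # participant_id, scene, subscale, rating

    @property
    def participants(self) -> list[str]:
        return sorted(self.profiles)


def _rng(config_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config_seed & 0x7FFFFFFF, *key]))


# ---------------------------------------------------------------------------
# Participant physiology


def generate_participant_profile(
    seed: int, config: SyntheticConfig, participant: str | None = None
) -> CalibrationProfile:
    """Draw a per-channel resting tone and MVIC amplitude for one
    participant; deterministic for a fixed seed."""
    config.validate()
    rng = _rng(config.seed, 1, seed)
    lo_t, hi_t = config.baseline_tone_range
    lo_m, hi_m = config.mvic_range
    tone = rng.uniform(lo_t, hi_t, size=N_CHANNELS)
    mvic = rng.uniform(lo_m, hi_m, size=N_CHANNELS)
    return CalibrationProfile(participant or f"P{seed:03d}", tone, mvic)


# ---------------------------------------------------------------------------
# Expression scripts


def generate_expression_script(
    scene: str,
    n_steps: int,
    config: SyntheticConfig,
    seed: int,
    participant: str = "P000",
) -> ExpressionScript:
    """Two-state renewal process: from the neutral background a burst starts
    at each step with the scene's onset probability; its class follows the
    scene's mixture and its length is uniform over ``burst_duration_range``."""
    if scene not in SCENES:
        raise ValueError(f"unknown scene {scene!r}; expected one of {SCENES}")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    config.validate()
    rng = _rng(config.seed, 2, seed)
    onset = config.burst_onset_prob[scene]
    mix = np.asarray(config.burst_mix[scene], dtype=float)
    if mix.sum() > 0:
        mix = mix / mix.sum()
    lo, hi = config.burst_duration_range
    labels: list[str] = []
    t = 0
    while t < n_steps:
        if onset > 0 and mix.sum() > 0 and rng.random() < onset:
            cls = NON_NEUTRAL[rng.choice(3, p=mix)]
            length = int(rng.integers(lo, hi + 1))
            length = min(length, n_steps - t)
            labels.extend([cls] * length)
            t += length
        else:
            labels.append("neutral")
            t += 1
    return ExpressionScript(participant, scene, labels, config.window_duration)


# ---------------------------------------------------------------------------
# Signal rendering


def _hann(n: int) -> np.ndarray:
    # raised-cosine rise-and-fall over n samples, endpoints at 0
    return 0.5 - 0.5 * np.cos(2 * np.pi * (np.arange(n) + 0.5) / n)


def render_femg(
    script: ExpressionScript,
    profile: CalibrationProfile,
    config: SyntheticConfig,
    seed: int | None = None,
) -> MultiChannelRecording:
    """Render a script into a 7-channel amplitude recording.

    Each maximal non-neutral run becomes one burst: a Hann envelope spanning
    the run, peaking at ``burst_peak_fraction`` (jittered) of the involved
    channels' dynamic range above tone.  Zero-mean Gaussian noise with
    sd = peak / snr is added and the result rectified at zero.
    """
    if script.participant != profile.participant:
        raise ValueError(
            f"participant mismatch: script {script.participant!r} vs "
            f"profile {profile.participant!r}"
        )
    config.validate()
    rng = _rng(config.seed, 3, seed if seed is not None else 0, len(script.labels))
    spw = int(round(script.window_duration * config.sample_rate))  # samples per step
    n = script.n_steps * spw
    tone = profile.neutral_baseline
    dyn = profile.mvic - profile.neutral_baseline
    x = np.tile(tone, (n, 1))

    ids = np.array([0 if lbl == "neutral" else 1 for lbl in script.labels])
    # find runs of non-neutral with constant label
    t = 0
    while t < script.n_steps:
        lbl = script.labels[t]
        t2 = t
        while t2 < script.n_steps and script.labels[t2] == lbl:
            t2 += 1
        if lbl != "neutral":
            a, b = t * spw, t2 * spw
            env = _hann(b - a)
            peak = config.burst_peak_fraction * (
                1.0 + config.peak_jitter * rng.standard_normal()
            )
            peak = max(peak, 0.05)
            for ch in involved_channels(lbl):
                x[a:b, ch] += peak * dyn[ch] * env
        t = t2

    noise_sd = config.burst_peak_fraction * dyn / config.snr
    x += rng.standard_normal(x.shape) * noise_sd
    if config.crosstalk > 0:
        # simple symmetric mixing of each channel with the mean of the others
        mean_others = (x.sum(axis=1, keepdims=True) - x) / (N_CHANNELS - 1)
        x = (1 - config.crosstalk) * x + config.crosstalk * mean_others
    np.clip(x, 0.0, None, out=x)
    events = [Event(script.scene, 0, n)]
    return MultiChannelRecording(
        participant=script.participant,
        samples=x,
        sample_rate=config.sample_rate,
        events=events,
        scene=script.scene,
    )


def generate_calibration_session(
    profile: CalibrationProfile, config: SyntheticConfig, seed: int
) -> MultiChannelRecording:
    """Alternating calibration blocks: neutral interleaved with held maximal
    expressions (smile, frown, raised eyebrow), repeated ``calib_reps``
    times.  Maximal blocks drive involved channels to ~MVIC via a trapezoid
    envelope (10% rise, 80% plateau at full dynamic range, 10% fall)."""
    config.validate()
    rng = _rng(config.seed, 4, seed)
    spb = int(round(config.calib_block_duration * config.sample_rate))
    pattern = ["neutral", "smile", "neutral", "frown", "neutral", "raised_eyebrow"]
    blocks = pattern * config.calib_reps
    n = len(blocks) * spb
    tone = profile.neutral_baseline
    dyn = profile.mvic - profile.neutral_baseline
    x = np.tile(tone, (n, 1))
    ramp = max(1, spb // 10)
    env = np.ones(spb)
    env[:ramp] = np.linspace(0, 1, ramp, endpoint=False)
    env[-ramp:] = np.linspace(1, 0, ramp, endpoint=False)[::-1]
    events: list[Event] = []
    for k, lbl in enumerate(blocks):
        a = k * spb
        events.append(Event(lbl, a, a + spb))
        if lbl != "neutral":
            for ch in involved_channels(lbl):
                x[a : a + spb, ch] += dyn[ch] * env
    noise_sd = config.burst_peak_fraction * dyn / config.snr
    x += rng.standard_normal(x.shape) * noise_sd
    np.clip(x, 0.0, None, out=x)
    return MultiChannelRecording(
        participant=profile.participant,
        samples=x,
        sample_rate=config.sample_rate,
        events=events,
        scene="calibration",
    )


# ---------------------------------------------------------------------------
# Workload ratings


def generate_workload_ratings(
    features_df: pd.DataFrame, config: SyntheticConfig, seed: int
) -> pd.DataFrame:
    """Generate NASA-TLX ratings (long format) from participant x scene
    feature rows.

    rating = intercept + scene effect + participant random intercept
             + sum(planted_beta * z-scored feature) + noise, truncated to [0, 10].

    ``features_df`` must carry ``participant`` and ``scene`` columns plus the
    feature columns referenced by ``config.planted_betas``.
    """
    config.validate()
    for (_, fname) in config.planted_betas:
        if fname not in features_df.columns:
            raise KeyError(f"planted beta references unknown feature {fname!r}")
    rng = _rng(config.seed, 5, seed)
    participants = sorted(features_df["participant"].unique())
    rows = []
    # z-score referenced features across all participant x scene rows
    zcols: dict[str, np.ndarray] = {}
    for fname in {f for (_, f) in config.planted_betas}:
        col = features_df[fname].to_numpy(dtype=float)
        sd = col.std()
        zcols[fname] = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)
    for sub in config.subscales:
        b = dict(zip(participants, rng.normal(0, config.random_intercept_sd, len(participants))))
        eff = config.scene_effects.get(sub, {})
        planted = [(f, beta) for (s, f), beta in config.planted_betas.items() if s == sub]
        for i, row in enumerate(features_df.itertuples(index=False)):
            pid, scene = row.participant, row.scene
            mu = config.tlx_intercept + eff.get(scene, 0.0) + b[pid]
            for fname, beta in planted:
                mu += beta * zcols[fname][i]
            rating = float(np.clip(mu + rng.normal(0, config.noise_sd), 0.0, 10.0))
            rows.append({"participant_id": pid, "scene": scene, "subscale": sub, "rating": rating})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort assembly


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate a full cohort: per participant one calibration session, one
    baseline recording and four stressor-scene recordings with ground-truth
    scripts, plus NASA-TLX ratings derived from the script features."""
    config.validate()
    if config.n_participants < 2:
        raise ValueError("n_participants must be >= 2 (leave-one-out undefined)")
    profiles: dict[str, CalibrationProfile] = {}
    calibrations: dict[str, MultiChannelRecording] = {}
    recordings: dict[tuple[str, str], MultiChannelRecording] = {}
    scripts: dict[tuple[str, str], ExpressionScript] = {}
    feat_rows = []
    for i in range(config.n_participants):
        pid = f"P{i:03d}"
        profile = generate_participant_profile(i, config, participant=pid)
        profiles[pid] = profile
        calibrations[pid] = generate_calibration_session(profile, config, i)
        for j, scene in enumerate(COHORT_SCENES):
            dur = config.baseline_duration if scene == "baseline" else config.scene_duration
            n_steps = int(dur // config.window_duration)
            script = generate_expression_script(
                scene, n_steps, config, seed=i * len(COHORT_SCENES) + j, participant=pid
            )
            scripts[(pid, scene)] = script
            recordings[(pid, scene)] = render_femg(
                script, profile, config, seed=i * len(COHORT_SCENES) + j
            )
            row = {"participant": pid, "scene": scene}
            row.update(feat.compute_feature_vector(script.labels))
            feat_rows.append(row)
    script_features = pd.DataFrame(feat_rows)
    ratings = generate_workload_ratings(script_features, config, seed=0)
    return Cohort(config, profiles, calibrations, recordings, scripts, script_features, ratings)


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Serialize a cohort to CSV/JSON files under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for pid, rec in cohort.calibrations.items():
        write_recording(rec, outdir / f"{pid}_calibration.csv", outdir / f"{pid}_calibration.json")
    for (pid, scene), rec in cohort.recordings.items():
        write_recording(rec, outdir / f"{pid}_{scene}.csv", outdir / f"{pid}_{scene}.json")
    script_rows = [
        {"participant_id": pid, "scene": scene, "step_index": k, "label": lbl}
        for (pid, scene), script in sorted(cohort.scripts.items())
        for k, lbl in enumerate(script.labels)
    ]
    pd.DataFrame(script_rows).to_csv(outdir / "scripts.csv", index=False)
    cohort.ratings.to_csv(outdir / "ratings.csv", index=False)
    cohort.script_features.to_csv(outdir / "script_features.csv", index=False)
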