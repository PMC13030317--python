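"""End-to-end pipeline orchestration with reproducible run manifests.

Stages: simulate -> preprocess -> train -> infer -> features -> stats.
A single global seed fans out to per-stage seeds via
``stage_seed = SeedSequence([seed, stage_index])`` (first state word, masked
to 31 bits), so any stage can be rerun in isolation reproducibly.  The run
manifest records the config hash, stage seeds, library versions and a
sha256 checksum of every output file; identical config + seed reproduce
identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as featmod
from . import stats as statsmod
from .inference import predict_sequence, summarize_sequence, cohort_scene_table
from .io_preprocess import (
    MultiChannelRecording,
    WindowingParams,
    compute_calibration_profile,
    normalize,
    read_recording,
    segment_windows,
)
from .model import (
    ModelConfig,
    lopo_cross_validate,
    retrain_full,
    save_model,
    windows_to_arrays,
)
from .synth import Cohort, SyntheticConfig, generate_cohort, write_cohort
from .types import COHORT_SCENES

log = logging.getLogger("femg_xdyn")

STAGES = ("simulate", "preprocess", "train", "infer", "features", "stats")

#: Default feature subset for the per-feature workload models (the full 81 x 8
#: family is available with stats_features='all').
DEFAULT_STATS_FEATURES = [
    "ratio_smile",
    "ratio_neutral",
    "avg_burst_smile",
    "entropy",
    "switch_rate",
    "neutral_to_smile",
]


@dataclass
class RunConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    window_ms: float = 1000.0
    stride_ms: float | None = None
    stages: tuple[str, ...] = STAGES
    run_lopo: bool = True
    fdr_q: float = 0.05
    fdr_family: str = "all"
    n_components: int = 2
    stats_features: list[str] | str = field(default_factory=lambda: list(DEFAULT_STATS_FEATURES))
    out_dir: str = "runs/out"
    seed: int = 0

    def windowing(self) -> WindowingParams:
        fs = self.synthetic.sample_rate
        w = int(round(self.window_ms / 1000.0 * fs))
        s = w if self.stride_ms is None else int(round(self.stride_ms / 1000.0 * fs))
        return WindowingParams(w, s)


def stage_seed(seed: int, stage: str) -> int:
    return int(np.random.SeedSequence([seed & 0x7FFFFFFF, STAGES.index(stage)]).generate_state(1)[0] & 0x7FFFFFFF)


def validate_config(config: RunConfig) -> list[str]:
    """Report-only schema check with actionable messages."""
    problems: list[str] = []
    try:
        config.synthetic.validate()
    except ValueError as exc:
        problems.append(f"synthetic: {exc}")
    try:
        config.model.validate()
    except ValueError as exc:
        problems.append(f"model: {exc}")
    try:
        params = config.windowing()
        pooled = params.w
        if config.model.architecture in ("cnn", "cnn-tcn", "cnn-lstm"):
            for _ in config.model.cnn_filters:
                pooled //= config.model.pool
            if pooled < 1:
                problems.append(
                    f"window of {params.w} samples incompatible with "
                    f"{len(config.model.cnn_filters)} pooling stages"
                )
    except ValueError as exc:
        problems.append(f"windowing: {exc}")
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        problems.append(f"unknown stage(s): {sorted(unknown)}")
    if config.run_lopo and "train" in config.stages and config.synthetic.n_participants < 3:
        problems.append("LOPO requires n_participants >= 3")
    return problems


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def config_to_yaml(config: RunConfig) -> str:
    d = dataclasses.asdict(config)
    d["synthetic"]["planted_betas"] = {
        f"{sub}::{feat}": beta for (sub, feat), beta in config.synthetic.planted_betas.items()
    }
    return yaml.safe_dump(d, sort_keys=True)


def config_from_yaml(text: str) -> RunConfig:
    d = yaml.safe_load(text)
    syn = d.pop("synthetic", {})
    if "planted_betas" in syn:
        syn["planted_betas"] = {
            tuple(k.split("::", 1)): v for k, v in syn["planted_betas"].items()
        }
    for key in ("baseline_tone_range", "mvic_range", "burst_duration_range"):
        if key in syn:
            syn[key] = tuple(syn[key])
    if "burst_mix" in syn:
        syn["burst_mix"] = {k: tuple(v) for k, v in syn["burst_mix"].items()}
    if "subscales" in syn:
        syn["subscales"] = tuple(syn["subscales"])
    mod = d.pop("model", {})
    for key in ("cnn_filters", "tcn_dilations"):
        if key in mod:
            mod[key] = tuple(mod[key])
    if "stages" in d:
        d["stages"] = tuple(d["stages"])
    return RunConfig(synthetic=SyntheticConfig(**syn), model=ModelConfig(**mod), **d)


def load_cohort_dir(sim_dir: str | Path) -> tuple[dict[str, MultiChannelRecording], dict[tuple[str, str], MultiChannelRecording], pd.DataFrame | None]:
    """Load calibration and scene recordings (plus ratings if present) from a
    simulate-stage output directory."""
    sim_dir = Path(sim_dir)
    calibrations: dict[str, MultiChannelRecording] = {}
    recordings: dict[tuple[str, str], MultiChannelRecording] = {}
    for csv in sorted(sim_dir.glob("*_calibration.csv")):
        rec = read_recording(csv, csv.with_suffix(".json"))
        calibrations[rec.participant] = rec
    for scene in COHORT_SCENES:
        for csv in sorted(sim_dir.glob(f"*_{scene}.csv")):
            rec = read_recording(csv, csv.with_suffix(".json"))
            recordings[(rec.participant, scene)] = rec
    ratings_path = sim_dir / "ratings.csv"
    ratings = pd.read_csv(ratings_path) if ratings_path.exists() else None
    return calibrations, recordings, ratings


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; return (and write) the manifest."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": hashlib.sha256(config_to_yaml(config).encode()).hexdigest(),
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "versions": _versions(),
        "stages": {},
        "outputs": {},
    }
    params = config.windowing()
    cohort: Cohort | None = None
    profiles = {}
    X = y = pids = None
    final_model = None
    sequences = []
    features_df = None
    ratings = None

    def _record(stage: str, t0: float, paths: list[Path], counts: dict | None = None) -> None:
        manifest["stages"][stage] = {
            "wall_s": round(time.time() - t0, 3),
            **({"rows": counts} if counts else {}),
        }
        for p in paths:
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)
        log.info("stage %s done in %.1fs", stage, time.time() - t0)

    if "simulate" in config.stages:
        t0 = time.time()
        syn = dataclasses.replace(config.synthetic, seed=stage_seed(config.seed, "simulate"))
        cohort = generate_cohort(syn)
        sim_dir = out / "sim"
        write_cohort(cohort, sim_dir)
        ratings = cohort.ratings
        _record("simulate", t0, sorted(sim_dir.glob("*")), {"participants": len(cohort.participants)})

    if "preprocess" in config.stages:
        t0 = time.time()
        if cohort is None:
            raise ValueError("preprocess stage requires the simulate stage (or a cohort)")
        windows = []
        for pid, calib in cohort.calibrations.items():
            profile = compute_calibration_profile(calib)
            profiles[pid] = profile
            windows.extend(segment_windows(normalize(calib, profile), params))
        X, y, pids = windows_to_arrays(windows)
        pre_dir = out / "preprocess"
        pre_dir.mkdir(exist_ok=True)
        summary = {
            "n_windows": int(len(y)),
            "window_samples": params.w,
            "stride_samples": params.s,
            "label_counts": {str(k): int(v) for k, v in zip(*np.unique(y, return_counts=True))},
        }
        (pre_dir / "windows_summary.json").write_text(json.dumps(summary, indent=1))
        _record("preprocess", t0, [pre_dir / "windows_summary.json"], {"windows": len(y)})

    if "train" in config.stages:
        t0 = time.time()
        if X is None:
            raise ValueError("train stage requires the preprocess stage")
        train_dir = out / "train"
        train_dir.mkdir(exist_ok=True)
        mcfg = dataclasses.replace(config.model, seed=stage_seed(config.seed, "train"))
        paths = []
        if config.run_lopo:
            lopo = lopo_cross_validate(X, y, pids, mcfg)
            fold_rows = []
            for f in lopo.folds:
                for split in ("train", "validation", "test"):
                    row = {"participant": f.test_participant, "split": split}
                    row.update(getattr(f, split).as_dict())
                    fold_rows.append(row)
            pd.DataFrame(fold_rows).to_csv(train_dir / "lopo_folds.csv", index=False)
            agg = {split: {k: list(v) for k, v in lopo.aggregate(split).items()} for split in ("train", "validation", "test")}
            (train_dir / "lopo_aggregate.json").write_text(json.dumps(agg, indent=1))
            paths += [train_dir / "lopo_folds.csv", train_dir / "lopo_aggregate.json"]
        final_model, hist, _ = retrain_full(X, y, pids, mcfg)
        save_model(final_model, train_dir / "final_model")
        pd.DataFrame({k: v for k, v in hist.items() if isinstance(v, list)}).to_csv(
            train_dir / "final_history.csv", index=False
        )
        paths += [train_dir / "final_model.npz", train_dir / "final_model.json", train_dir / "final_history.csv"]
        _record("train", t0, paths)

    if "infer" in config.stages:
        t0 = time.time()
        if final_model is None or cohort is None:
            raise ValueError("infer stage requires the train stage")
        seq_rows = []
        summaries = []
        for (pid, scene), rec in sorted(cohort.recordings.items()):
            nrec = normalize(rec, profiles[pid])
            seq = predict_sequence(final_model, nrec, params)
            sequences.append(seq)
            summaries.append(summarize_sequence(seq))
            seq_rows += [
                {"participant": pid, "scene": scene, "window_start_s": t, "label": lbl}
                for t, lbl in zip(seq.window_times, seq.labels)
            ]
        infer_dir = out / "infer"
        infer_dir.mkdir(exist_ok=True)
        pd.DataFrame(seq_rows).to_csv(infer_dir / "sequences.csv", index=False)
        table, agg = cohort_scene_table(summaries)
        table.to_csv(infer_dir / "scene_summaries.csv", index=False)
        agg.to_csv(infer_dir / "scene_aggregate.csv", index=False)
        _record("infer", t0, [infer_dir / p for p in ("sequences.csv", "scene_summaries.csv", "scene_aggregate.csv")],
                {"sequences": len(sequences)})

    if "features" in config.stages:
        t0 = time.time()
        if not sequences:
            raise ValueError("features stage requires the infer stage")
        rows = []
        for seq in sequences:
            row = {"participant": seq.participant, "scene": seq.scene}
            row.update(featmod.compute_feature_vector(seq.labels))
            rows.append(row)
        features_df = pd.DataFrame(rows)
        feat_dir = out / "features"
        feat_dir.mkdir(exist_ok=True)
        features_df.to_csv(feat_dir / "features.csv", index=False)
        (feat_dir / "feature_registry.json").write_text(
            json.dumps(featmod.feature_registry(), indent=1)
        )
        _record("features", t0, [feat_dir / "features.csv", feat_dir / "feature_registry.json"],
                {"rows": len(features_df)})

    if "stats" in config.stages:
        t0 = time.time()
        if features_df is None:
            raise ValueError("stats stage requires the features stage")
        if ratings is None:
            raise ValueError("stats stage requires a ratings table (ratings.csv missing)")
        stats_dir = out / "stats"
        stats_dir.mkdir(exist_ok=True)
        std = statsmod.standardize(features_df)
        pca = statsmod.run_pca(std, config.n_components)
        pca.loadings.to_csv(stats_dir / "pca_loadings.csv")
        pca.scores.to_csv(stats_dir / "pca_scores.csv", index=False)
        pd.DataFrame({"component": [f"PC{i+1}" for i in range(config.n_components)],
                      "explained_variance_ratio": pca.explained_variance_ratio}).to_csv(
            stats_dir / "pca_variance.csv", index=False)
        statsmod.plot_pc_by_scene(pca, str(stats_dir / "pc_scores_by_scene.png"))
        scene_rows = []
        for pc in (f"PC{i+1}" for i in range(config.n_components)):
            res = statsmod.fit_scene_model(pca.scores, pc)
            for e in res.effects:
                scene_rows.append({"component": pc, "scene": e.term, "beta": e.beta, "se": e.se, "p": e.p})
        pd.DataFrame(scene_rows).to_csv(stats_dir / "scene_contrasts.csv", index=False)
        feats = std.feature_columns if config.stats_features == "all" else [
            f for f in config.stats_features if f in std.feature_columns
        ]
        results = statsmod.fit_feature_workload_models(std, ratings, features=feats)
        table = statsmod.attach_fdr(results, config.fdr_q, family=config.fdr_family)
        table.to_csv(stats_dir / "workload_models.csv", index=False)
        paths = [stats_dir / p for p in (
            "pca_loadings.csv", "pca_scores.csv", "pca_variance.csv",
            "scene_contrasts.csv", "workload_models.csv")]
        _record("stats", t0, paths, {"models": len(results)})

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _versions() -> dict[str, str]:
    import sklearn
    import statsmodels

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
    }
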