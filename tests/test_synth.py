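"""Generator tests: determinism, renewal-process occupancy, FACS-consistent
rendering, calibration sessions, ratings model, and cohort assembly."""

import numpy as np
import pandas as pd
import pytest

from femg_xdyn.features import compute_feature_vector
from femg_xdyn.synth import (
    SyntheticConfig,
    generate_calibration_session,
    generate_cohort,
    generate_expression_script,
    generate_participant_profile,
    generate_workload_ratings,
    render_femg,
    write_cohort,
)
from femg_xdyn.types import CHANNELS, COHORT_SCENES, involved_channels

from conftest import small_synth_config


class TestProfiles:
    def test_same_seed_identical(self):
        cfg = small_synth_config()
        a = generate_participant_profile(5, cfg)
        b = generate_participant_profile(5, cfg)
        np.testing.assert_array_equal(a.neutral_baseline, b.neutral_baseline)
        np.testing.assert_array_equal(a.mvic, b.mvic)

    def test_degenerate_interval(self):
        cfg = small_synth_config(baseline_tone_range=(0.2, 0.2), mvic_range=(1.2, 1.2))
        p = generate_participant_profile(0, cfg)
        np.testing.assert_allclose(p.neutral_baseline, 0.2)
        np.testing.assert_allclose(p.mvic, 1.2)

    def test_draws_stay_within_range(self):
        cfg = small_synth_config(baseline_tone_range=(0.1, 0.3), mvic_range=(1.0, 1.4))
        tones = np.concatenate(
            [generate_participant_profile(i, cfg).neutral_baseline for i in range(150)]
        )
        assert tones.min() >= 0.1 and tones.max() <= 0.3

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError, match="inverted"):
            small_synth_config(mvic_range=(1.4, 1.0)).validate()

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ValueError, match="strictly above"):
            small_synth_config(baseline_tone_range=(0.1, 0.9), mvic_range=(0.8, 1.5)).validate()


class TestScripts:
    def test_zero_rate_limit_all_neutral(self):
        cfg = small_synth_config(burst_onset_prob={s: 0.0 for s in
                                 ("baseline", "emotional", "cognitive", "physical", "dual", "recovery")})
        script = generate_expression_script("baseline", 200, cfg, seed=0)
        assert set(script.labels) == {"neutral"}

    def test_fixed_seed_identical(self):
        cfg = small_synth_config()
        a = generate_expression_script("physical", 100, cfg, seed=9)
        b = generate_expression_script("physical", 100, cfg, seed=9)
        assert a.labels == b.labels

    def test_scene_occupancy_ordering_monte_carlo(self):
        """At 10^4 steps the non-neutral fraction reproduces the planted
        scene ordering: cognitive < baseline ~ emotional < physical ~ dual."""
        cfg = small_synth_config()
        occ = {}
        for scene in COHORT_SCENES:
            script = generate_expression_script(scene, 10_000, cfg, seed=1)
            occ[scene] = np.mean([lbl != "neutral" for lbl in script.labels])
        assert occ["cognitive"] < occ["baseline"] < occ["physical"]
        assert occ["cognitive"] < occ["emotional"] < occ["dual"]

    def test_scene_class_mixtures(self):
        cfg = small_synth_config()
        phys = generate_expression_script("physical", 10_000, cfg, seed=2).labels
        emo = generate_expression_script("emotional", 10_000, cfg, seed=3).labels
        phys_nn = [l for l in phys if l != "neutral"]
        emo_nn = [l for l in emo if l != "neutral"]
        assert phys_nn.count("smile") / len(phys_nn) > 0.6
        assert emo_nn.count("raised_eyebrow") / len(emo_nn) > emo_nn.count("smile") / len(emo_nn)

    def test_unknown_scene_rejected(self):
        with pytest.raises(ValueError, match="unknown scene"):
            generate_expression_script("lobby", 10, small_synth_config(), seed=0)

    def test_occupancy_converges_to_renewal_prediction(self):
        """Occupancy at 10^4 steps is within 3 Monte-Carlo SE of the renewal
        prediction p*L / (1 - p + p*L): each background decision yields one
        neutral step (prob 1-p) or a burst of mean length L (prob p)."""
        cfg = small_synth_config()
        p = cfg.burst_onset_prob["physical"]
        L = np.mean(np.arange(cfg.burst_duration_range[0], cfg.burst_duration_range[1] + 1))
        expected = p * L / (1 - p + p * L)
        labels = generate_expression_script("physical", 10_000, cfg, seed=4).labels
        occ = np.mean([l != "neutral" for l in labels])
        # bursts arrive in blocks: effective sample count ~ n/L
        se = np.sqrt(expected * (1 - expected) / (10_000 / L))
        assert abs(occ - expected) < 3 * se


class TestRendering:
    def _setup(self, labels, seed=0, **kw):
        cfg = small_synth_config(**kw)
        profile = generate_participant_profile(0, cfg, participant="P000")
        from femg_xdyn.synth import ExpressionScript
        script = ExpressionScript("P000", "baseline", labels, cfg.window_duration)
        return render_femg(script, profile, cfg, seed=seed), profile, cfg

    def test_smile_raises_zygomaticus_vs_neutral(self):
        rec_s, prof, _ = self._setup(["smile"] * 30)
        rec_n, _, _ = self._setup(["neutral"] * 30)
        zyg = [i for i, ch in enumerate(CHANNELS) if ch.startswith("zygomaticus")]
        assert rec_s.samples[:, zyg].mean() > rec_n.samples[:, zyg].mean() + 0.05

    def test_noise_free_neutral_equals_tone(self):
        rec, prof, _ = self._setup(["neutral"] * 10, snr=1e12)
        np.testing.assert_allclose(
            rec.samples, np.broadcast_to(prof.neutral_baseline, rec.samples.shape), rtol=1e-6
        )

    def test_frown_elevates_brow_channels_only(self):
        rec_f, prof, cfg = self._setup(["frown"] * 30, seed=1)
        rec_n, _, _ = self._setup(["neutral"] * 30, seed=1)
        diff = rec_f.samples.mean(axis=0) - rec_n.samples.mean(axis=0)
        for ch in involved_channels("frown"):
            assert diff[ch] > 0.05
        noise_se = (cfg.burst_peak_fraction * (prof.mvic - prof.neutral_baseline)
                    / cfg.snr / np.sqrt(rec_f.n_samples))
        for ch in involved_channels("smile"):
            if ch not in involved_channels("frown"):
                assert abs(diff[ch]) < max(2 * noise_se[ch], 1e-3)

    def test_participant_mismatch_rejected(self):
        cfg = small_synth_config()
        profile = generate_participant_profile(0, cfg, participant="P001")
        from femg_xdyn.synth import ExpressionScript
        script = ExpressionScript("P000", "baseline", ["neutral"], cfg.window_duration)
        with pytest.raises(ValueError, match="mismatch"):
            render_femg(script, profile, cfg)

    def test_sample_count_and_nonnegativity(self):
        rec, _, cfg = self._setup(["smile", "neutral"] * 5)
        assert rec.n_samples == 10 * int(cfg.window_duration * cfg.sample_rate)
        assert rec.samples.min() >= 0.0


class TestCalibrationSession:
    def test_contains_all_four_block_labels(self):
        cfg = small_synth_config()
        prof = generate_participant_profile(0, cfg, participant="P000")
        rec = generate_calibration_session(prof, cfg, seed=0)
        assert {e.label for e in rec.events} == {"neutral", "smile", "frown", "raised_eyebrow"}

    def test_max_smile_blocks_reach_mvic(self):
        cfg = small_synth_config(snr=40.0)
        prof = generate_participant_profile(1, cfg, participant="P000")
        rec = generate_calibration_session(prof, cfg, seed=1)
        zyg = [i for i, ch in enumerate(CHANNELS) if ch.startswith("zygomaticus")]
        smile = np.concatenate([rec.samples[e.start:e.end] for e in rec.events if e.label == "smile"])
        p95 = np.percentile(smile[:, zyg], 95, axis=0)
        np.testing.assert_allclose(p95, prof.mvic[zyg], rtol=0.05)

    def test_neutral_blocks_stay_at_tone(self):
        cfg = small_synth_config(snr=40.0)
        prof = generate_participant_profile(2, cfg, participant="P000")
        rec = generate_calibration_session(prof, cfg, seed=2)
        neutral = np.concatenate([rec.samples[e.start:e.end] for e in rec.events if e.label == "neutral"])
        np.testing.assert_allclose(np.median(neutral, axis=0), prof.neutral_baseline, atol=0.02)


class TestRatings:
    def _features(self, n=20):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(n):
            for scene in COHORT_SCENES:
                rows.append({"participant": f"P{i:03d}", "scene": scene,
                             "ratio_smile": rng.random(), "entropy": rng.random()})
        return pd.DataFrame(rows)

    def test_deterministic_part_exact(self):
        cfg = small_synth_config(planted_betas={}, noise_sd=0.0, random_intercept_sd=0.0)
        ratings = generate_workload_ratings(self._features(), cfg, seed=0)
        phys = ratings[(ratings.subscale == "physical") & (ratings.scene == "physical")]
        expected = cfg.tlx_intercept + cfg.scene_effects["physical"]["physical"]
        assert (phys.rating == expected).all()
        base = ratings[(ratings.subscale == "physical") & (ratings.scene == "baseline")]
        assert (base.rating == cfg.tlx_intercept).all()

    def test_ratings_within_bounds(self):
        cfg = small_synth_config(noise_sd=4.0, random_intercept_sd=4.0)
        ratings = generate_workload_ratings(self._features(), cfg, seed=1)
        assert ratings.rating.between(0, 10).all()

    def test_planted_negative_beta_produces_negative_correlation(self):
        cfg = small_synth_config(planted_betas={("physical", "ratio_smile"): -1.0})
        feats = self._features(n=200)
        ratings = generate_workload_ratings(feats, cfg, seed=2)
        phys = ratings[ratings.subscale == "physical"].reset_index(drop=True)
        merged = feats.merge(phys, left_on=["participant", "scene"],
                             right_on=["participant_id", "scene"])
        assert merged["ratio_smile"].corr(merged["rating"]) < -0.1

    def test_unknown_planted_feature_rejected(self):
        cfg = small_synth_config(planted_betas={("physical", "nope"): 1.0})
        with pytest.raises(KeyError, match="nope"):
            generate_workload_ratings(self._features(), cfg, seed=0)


class TestCohort:
    def test_counts(self, small_cohort):
        n = small_cohort.config.n_participants
        assert len(small_cohort.calibrations) == n
        assert len(small_cohort.recordings) == n * 5  # baseline + 4 stressors
        assert len(small_cohort.scripts) == n * 5
        assert set(small_cohort.ratings.subscale) == set(small_cohort.config.subscales)

    def test_single_participant_rejected(self):
        with pytest.raises(ValueError, match="n_participants"):
            generate_cohort(small_synth_config(n_participants=1))

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = small_synth_config(n_participants=2, scene_duration=10.0, baseline_duration=10.0)
        for d in ("a", "b"):
            write_cohort(generate_cohort(cfg), tmp_path / d)
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name

    def test_facs_consistency_involved_channels_elevated(self, small_cohort):
        """During each expression's bursts the involved channels' mean
        exceeds that channel's neutral-frame mean."""
        cohort = small_cohort
        cfg = cohort.config
        spw = int(cfg.window_duration * cfg.sample_rate)
        pid = cohort.participants[0]
        for scene in ("physical", "emotional"):
            rec = cohort.recordings[(pid, scene)]
            labels = cohort.scripts[(pid, scene)].labels
            per_class = {}
            for cls in set(labels):
                idx = np.concatenate([np.arange(k * spw, (k + 1) * spw)
                                      for k, l in enumerate(labels) if l == cls])
                per_class[cls] = rec.samples[idx].mean(axis=0)
            for cls, mean in per_class.items():
                if cls == "neutral":
                    continue
                for ch in involved_channels(cls):
                    assert mean[ch] > per_class["neutral"][ch]
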