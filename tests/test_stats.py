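"""Statistics-stage tests: standardization, PCA, mixed-effects scene and
workload models (parameter recovery at reduced scale), and BH-FDR against a
brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from femg_xdyn.stats import (
    apply_fdr,
    attach_fdr,
    fit_feature_workload_models,
    fit_scene_model,
    run_pca,
    standardize,
)


def _feature_frame(values: dict[str, list[float]]) -> pd.DataFrame:
    n = len(next(iter(values.values())))
    base = {"participant": [f"P{i}" for i in range(n)], "scene": ["baseline"] * n}
    return pd.DataFrame({**base, **values})


class TestStandardize:
    def test_hand_computed_population_zscore(self):
        std = standardize(_feature_frame({"f": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(std.data["f"], [-1.2247448, 0.0, 1.2247448], atol=1e-6)

    def test_constant_column_dropped_and_logged(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            std = standardize(_feature_frame({"f": [1.0, 2.0], "const": [5.0, 5.0]}))
        assert std.dropped == ["const"]
        assert "const" not in std.feature_columns

    def test_retained_columns_have_unit_moments(self):
        rng = np.random.default_rng(0)
        df = _feature_frame({f"f{i}": list(rng.random(50)) for i in range(5)})
        std = standardize(df)
        for c in std.feature_columns:
            assert abs(std.data[c].mean()) < 1e-9
            assert abs(std.data[c].std(ddof=0) - 1) < 1e-9

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            standardize(_feature_frame({"f": [1.0]}))


class TestPCA:
    def test_collinear_columns_put_all_variance_on_pc1(self):
        x = list(np.linspace(0, 1, 30))
        std = standardize(_feature_frame({"a": x, "b": [2 * v for v in x]}))
        res = run_pca(std, 2)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_gaussian_spreads_variance(self):
        rng = np.random.default_rng(1)
        df = _feature_frame({f"f{i}": list(rng.standard_normal(2000)) for i in range(5)})
        res = run_pca(standardize(df), 5)
        np.testing.assert_allclose(res.explained_variance_ratio, 0.2, atol=0.03)
        assert (np.diff(res.explained_variance_ratio) <= 1e-12).all()

    def test_full_reconstruction(self):
        rng = np.random.default_rng(2)
        df = _feature_frame({f"f{i}": list(rng.standard_normal(40)) for i in range(4)})
        std = standardize(df)
        res = run_pca(std, 4)
        X = std.data[std.feature_columns].to_numpy()
        recon = res.scores[[f"PC{i+1}" for i in range(4)]].to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(recon, X - X.mean(axis=0), atol=1e-9)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(3)
        df = _feature_frame({f"f{i}": list(rng.standard_normal(60)) for i in range(3)})
        res = run_pca(standardize(df), 2)
        for pc in res.loadings.columns:
            col = res.loadings[pc].to_numpy()
            assert col[np.abs(col).argmax()] > 0

    def test_rank_deficiency_rejected(self):
        std = standardize(_feature_frame({"a": [1.0, 2.0, 3.0]}))
        with pytest.raises(ValueError, match="n_components"):
            run_pca(std, 2)


def _simulate_scores(n_participants=60, shift=-2.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_participants):
        b = rng.normal(0, 1)
        for scene in ("baseline", "cognitive", "physical"):
            mu = b + (shift if scene == "cognitive" else 0.0)
            rows.append({"participant": f"P{i:03d}", "scene": scene,
                         "PC1": mu + rng.normal(0, 1)})
    return pd.DataFrame(rows)


class TestSceneModel:
    def test_recovers_planted_cognitive_shift(self):
        res = fit_scene_model(_simulate_scores(100, -2.0), "PC1")
        eff = res.effect("cognitive")
        assert eff.beta == pytest.approx(-2.0, abs=0.3)
        assert res.converged

    def test_null_p_values_calibrated(self):
        hits = 0
        reps = 100
        for rep in range(reps):
            res = fit_scene_model(_simulate_scores(25, 0.0, seed=rep), "PC1")
            hits += res.effect("cognitive").p < 0.05
        assert 0.01 <= hits / reps <= 0.12

    def test_single_scene_rejected(self):
        df = _simulate_scores(5)
        with pytest.raises(ValueError, match="2 scenes"):
            fit_scene_model(df[df.scene == "baseline"], "PC1")


class TestWorkloadModels:
    def _cohort(self, beta=-1.0, n=80, seed=0):
        rng = np.random.default_rng(seed)
        rows, ratings = [], []
        for i in range(n):
            b = rng.normal(0, 1)
            for scene in ("baseline", "cognitive", "physical"):
                x = rng.normal(0, 1)
                rows.append({"participant": f"P{i:03d}", "scene": scene, "feat": x})
                ratings.append({"participant_id": f"P{i:03d}", "scene": scene,
                                "subscale": "physical",
                                "rating": 5 + b + beta * x + rng.normal(0, 0.5)})
        return pd.DataFrame(rows), pd.DataFrame(ratings)

    def test_recovers_planted_beta_with_correct_sign(self):
        feats, ratings = self._cohort()
        std = standardize(feats)
        res = fit_feature_workload_models(std, ratings, features=["feat"])
        eff = res[0].effect("x")
        assert eff.beta < 0
        assert eff.beta == pytest.approx(-1.0, abs=0.3)
        assert res[0].converged

    def test_unknown_feature_rejected(self):
        feats, ratings = self._cohort(n=5)
        std = standardize(feats)
        with pytest.raises(KeyError):
            fit_feature_workload_models(std, ratings, features=["nope"])

    def test_attach_fdr_restricts_family_to_feature_terms(self):
        feats, ratings = self._cohort(n=30)
        std = standardize(feats)
        res = fit_feature_workload_models(std, ratings, features=["feat"])
        table = attach_fdr(res)
        feature_terms = table[table.term.str.startswith("x")]
        scene_terms = table[~table.term.str.startswith("x")]
        assert feature_terms["q"].notna().all()
        assert scene_terms["q"].isna().all()


class TestFDR:
    def test_hand_case(self):
        q, mask = apply_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, 0.04)
        assert mask.all()

    def test_single_p_identity(self):
        q, _ = apply_fdr(np.array([0.05]))
        assert q[0] == pytest.approx(0.05)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            apply_fdr(np.array([0.5, 1.2]))

    def test_matches_brute_force_oracle(self):
        def bh_oracle(p):
            m = len(p)
            order = np.argsort(p)
            q = np.empty(m)
            running = 1.0
            for rank_from_top, idx in enumerate(order[::-1]):
                rank = m - rank_from_top
                running = min(running, p[idx] * m / rank)
                q[idx] = running
            return q

        rng = np.random.default_rng(0)
        for _ in range(300):
            p = rng.random(rng.integers(1, 40))
            q, _ = apply_fdr(p)
            np.testing.assert_allclose(q, bh_oracle(p), atol=1e-12)
            assert (q >= p - 1e-12).all()
            # monotone in p
            order = np.argsort(p)
            assert (np.diff(q[order]) >= -1e-12).all()
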