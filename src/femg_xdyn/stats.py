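"""Workload statistics: feature standardization, PCA, linear mixed-effects
models and Benjamini-Hochberg FDR.

Observations are participant x scene rows.  Features are z-scored
(population SD) across all rows before modeling, so fixed-effect estimates
are in rating units per one SD of the feature.  Mixed models use a
participant random intercept and are estimated by REML with Powell's
derivative-free optimizer (statsmodels MixedLM).  The FDR family defaults to
all (feature x subscale) feature-effect p-values jointly — the feature main
effect plus each feature-by-scene interaction — with per-subscale families
available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning


@dataclass
class StandardizedFeatureTable:
    """z-scored feature columns over participant x scene rows; constant
    columns are dropped and logged."""

    data: pd.DataFrame  # participant, scene + z-scored feature columns
    dropped: list[str]
    means: pd.Series
    sds: pd.Series

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("participant", "scene")]


def standardize(features: pd.DataFrame) -> StandardizedFeatureTable:
    """Per-column z-score (population SD) over all observations."""
    if len(features) < 2:
        raise ValueError("need >= 2 observations to standardize")
    meta = features[["participant", "scene"]].reset_index(drop=True)
    cols = [c for c in features.columns if c not in ("participant", "scene")]
    X = features[cols].astype(float).reset_index(drop=True)
    sds = X.std(ddof=0)
    dropped = list(sds.index[sds == 0])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance feature column(s)")
    kept = [c for c in cols if c not in dropped]
    means = X[kept].mean()
    Z = (X[kept] - means) / sds[kept]
    return StandardizedFeatureTable(pd.concat([meta, Z], axis=1), dropped, means, sds[kept])


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # features x components
    scores: pd.DataFrame  # observations x components (+ participant, scene)
    explained_variance_ratio: np.ndarray


def run_pca(std_table: StandardizedFeatureTable, n_components: int = 2) -> PCAResult:
    """PCA of the standardized feature matrix.  Components are ordered by
    explained variance; each component's sign is fixed so its
    largest-magnitude loading is positive."""
    cols = std_table.feature_columns
    X = std_table.data[cols].to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 observations")
    max_rank = min(X.shape[0], len(cols))
    if n_components > max_rank:
        raise ValueError(f"n_components={n_components} exceeds rank bound {max_rank}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T.copy()  # features x components
    for k in range(n_components):
        j = np.abs(loadings[:, k]).argmax()
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    pc_names = [f"PC{k + 1}" for k in range(n_components)]
    scores_df = std_table.data[["participant", "scene"]].copy()
    for k, name in enumerate(pc_names):
        scores_df[name] = scores[:, k]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=cols, columns=pc_names),
        scores=scores_df,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


# ---------------------------------------------------------------------------
# Mixed-effects models


@dataclass
class FixedEffect:
    term: str
    beta: float
    se: float
    p: float
    q: float | None = None


@dataclass
class MixedModelResult:
    feature: str
    subscale: str
    effects: list[FixedEffect]
    random_intercept_var: float
    converged: bool
    n_obs: int
    note: str = ""

    def effect(self, term: str) -> FixedEffect:
        for e in self.effects:
            if e.term == term:
                return e
        raise KeyError(term)


def _fit_mixedlm(formula: str, df: pd.DataFrame, groups: pd.Series):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(formula, df, groups=groups)
        return model.fit(reml=True, method="powell", maxiter=2000, disp=False)


def fit_scene_model(
    scores: pd.DataFrame, value_col: str, baseline: str = "baseline"
) -> MixedModelResult:
    """Scene-contrast mixed model: value ~ scene (baseline reference) with a
    participant random intercept.  Returns per-scene fixed effects."""
    df = scores.rename(columns={value_col: "y"}).copy()
    if df["scene"].nunique() < 2:
        raise ValueError("need >= 2 scenes including baseline")
    if baseline not in set(df["scene"]):
        raise ValueError(f"baseline scene {baseline!r} absent")
    if df["participant"].nunique() < 2:
        raise ValueError("need >= 2 participants")
    formula = f"y ~ C(scene, Treatment('{baseline}'))"
    res = _fit_mixedlm(formula, df, df["participant"])
    effects = []
    for term in res.fe_params.index:
        if "scene" in term:
            scene = term.split("[T.")[-1].rstrip("]")
            effects.append(
                FixedEffect(scene, float(res.fe_params[term]), float(res.bse[term]), float(res.pvalues[term]))
            )
    return MixedModelResult(
        feature=value_col,
        subscale="",
        effects=effects,
        random_intercept_var=float(res.cov_re.iloc[0, 0]),
        converged=bool(res.converged),
        n_obs=len(df),
    )


def fit_feature_workload_models(
    std_features: StandardizedFeatureTable,
    ratings: pd.DataFrame,
    features: list[str] | None = None,
    subscales: list[str] | None = None,
    interaction: bool = True,
    baseline: str = "baseline",
) -> list[MixedModelResult]:
    """For each (feature, subscale) pair fit
    ``rating ~ feature * scene + (1 | participant)`` by REML/Powell.

    ``ratings`` is long-format (participant_id, scene, subscale, rating).
    Rows with missing ratings are dropped listwise per model.  Convergence
    failures and collinear features are flagged, not dropped.
    """
    feats = features or std_features.feature_columns
    subs = subscales or sorted(ratings["subscale"].unique())
    unknown = set(feats) - set(std_features.feature_columns)
    if unknown:
        raise KeyError(f"unknown feature column(s): {sorted(unknown)}")
    results: list[MixedModelResult] = []
    wide = ratings.rename(columns={"participant_id": "participant"})
    for sub in subs:
        sub_ratings = wide[wide["subscale"] == sub][["participant", "scene", "rating"]]
        merged_base = std_features.data.merge(sub_ratings, on=["participant", "scene"], how="inner")
        for feature in feats:
            df = merged_base[["participant", "scene", "rating", feature]].rename(
                columns={feature: "x"}
            ).dropna()
            note = ""
            if df["x"].std(ddof=0) == 0:
                results.append(
                    MixedModelResult(feature, sub, [], 0.0, False, len(df), note="constant feature")
                )
                continue
            op = "*" if interaction else "+"
            formula = f"rating ~ x {op} C(scene, Treatment('{baseline}'))"
            try:
                res = _fit_mixedlm(formula, df, df["participant"])
            except Exception as exc:  # singular fits etc.
                results.append(
                    MixedModelResult(feature, sub, [], 0.0, False, len(df), note=f"fit error: {exc}")
                )
                continue
            effects = []
            for term in res.fe_params.index:
                if term == "Intercept":
                    continue
                beta, se, p = float(res.fe_params[term]), float(res.bse[term]), float(res.pvalues[term])
                if not np.isfinite(se) or se <= 0:
                    note = "degenerate SE"
                effects.append(FixedEffect(term, beta, se, p))
            results.append(
                MixedModelResult(
                    feature,
                    sub,
                    effects,
                    float(res.cov_re.iloc[0, 0]),
                    bool(res.converged),
                    len(df),
                    note=note,
                )
            )
    return results


# ---------------------------------------------------------------------------
# FDR


def apply_fdr(pvalues: np.ndarray, q_threshold: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted q-values and the q < threshold
    significance mask."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=q_threshold, method="fdr_bh")
    return q, q < q_threshold


def attach_fdr(
    results: list[MixedModelResult],
    q_threshold: float = 0.05,
    family: str = "all",
    terms: str = "feature",
) -> pd.DataFrame:
    """Assemble a long results table and attach BH q-values.

    ``family='all'`` corrects all feature-effect p-values jointly across
    subscales; ``family='per_subscale'`` corrects within each subscale.
    ``terms='feature'`` restricts the family to the feature main effect and
    feature x scene interactions (scene main effects are excluded).
    """
    rows = []
    for r in results:
        for e in r.effects:
            is_feature_term = e.term == "x" or e.term.startswith("x:")
            rows.append(
                {
                    "feature": r.feature,
                    "subscale": r.subscale,
                    "term": e.term,
                    "beta": e.beta,
                    "se": e.se,
                    "p": e.p,
                    "converged": r.converged,
                    # degenerate fits (non-finite p) stay in the table, flagged
                    # by their convergence status, but cannot enter the family
                    "in_family": (is_feature_term if terms == "feature" else True)
                    and np.isfinite(e.p),
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["q"] = np.nan
    table["significant"] = False
    if family == "per_subscale":
        groups = [g.index for _, g in table[table["in_family"]].groupby("subscale")]
    else:
        groups = [table[table["in_family"]].index]
    for idx in groups:
        if len(idx) == 0:
            continue
        q, mask = apply_fdr(table.loc[idx, "p"].to_numpy(), q_threshold)
        table.loc[idx, "q"] = q
        table.loc[idx, "significant"] = mask
    return table.drop(columns=["in_family"])


def plot_pc_by_scene(pca_result: PCAResult, path: str) -> None:
    """Boxplots of PC scores by scene (one panel per component)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pcs = [c for c in pca_result.scores.columns if c.startswith("PC")]
    fig, axes = plt.subplots(1, len(pcs), figsize=(5 * len(pcs), 4), squeeze=False)
    scenes = sorted(pca_result.scores["scene"].unique())
    for ax, pc in zip(axes[0], pcs):
        data = [pca_result.scores.loc[pca_result.scores["scene"] == s, pc] for s in scenes]
        ax.boxplot(data, tick_labels=scenes)
        ax.set_title(pc)
        ax.set_ylabel("score")
        ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
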