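"""Explanation pipeline: cluster patch embeddings into human-reviewable
histologic features, quantify how much variance in model risk scores those
features explain, and evaluate single features as standalone prognostic
scores.

Patch embeddings come from a pluggable embedder (any deterministic
patch -> vector map).  The default is hand-crafted texture statistics;
the trained prognostic encoder's pooled features are the alternative.
Case-level features are the percentages (0-100) of a case's tumor patches
assigned to each k-means cluster; rows over tumor-bearing cases sum to 100.

The "patch-level risk score" of a patch is the model applied to the
singleton bag containing it; with mean pooling, a case score is exactly the
mean of its patch-level scores, making this the natural decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import substream
from .roimask import patch_features

__all__ = [
    "EmbeddingSet",
    "TextureStatEmbedder",
    "EncoderEmbedder",
    "embed",
    "ClusterModel",
    "fit_clusters",
    "assign_clusters",
    "case_features",
    "VarianceReport",
    "explain_variance",
    "clinicopath_regression",
    "forward_stepwise",
    "select_k",
    "patch_score_summary",
    "single_feature_prognosis",
    "representative_patches",
]


@dataclass
class EmbeddingSet:
    ids: pd.DataFrame  # patch_id, case_id, slide_id, row, col
    vectors: np.ndarray  # (n_patches, dim)
    embedder_id: str

    def __post_init__(self):
        if len(self.ids) != len(self.vectors):
            raise ValueError("one vector per patch required")
        if not np.isfinite(self.vectors).all():
            raise ValueError("embeddings must be finite")


class TextureStatEmbedder:
    """Default embedder: channel moments + gradient statistics + a coarse
    gradient-orientation histogram.  Visually similar procedural textures
    embed nearby; no training involved."""

    embedder_id = "texture-stats"

    def __call__(self, patches: np.ndarray) -> np.ndarray:
        x = np.asarray(patches, dtype=float) / 255.0
        if x.ndim == 3:
            x = x[None]
        base = patch_features(np.asarray(patches))
        gray = x.mean(axis=3)
        gy = np.diff(gray, axis=1)[:, :, :-1]
        gx = np.diff(gray, axis=2)[:, :-1, :]
        ang = np.arctan2(gy, gx)  # orientation histogram, 4 bins
        mag = np.hypot(gy, gx)
        bins = ((ang + np.pi) / (2 * np.pi / 4)).astype(int) % 4
        hist = np.stack(
            [np.where(bins == b, mag, 0.0).sum(axis=(1, 2)) for b in range(4)], axis=1
        )
        hist /= np.maximum(hist.sum(axis=1, keepdims=True), 1e-9)
        return np.concatenate([base, hist], axis=1)


class EncoderEmbedder:
    """Embeddings from the trained prognostic encoder's pooled features."""

    def __init__(self, encoder, normalizer):
        self.encoder = encoder
        self.normalizer = normalizer
        self.embedder_id = "prognostic-encoder"

    def __call__(self, patches: np.ndarray) -> np.ndarray:
        from .survmodel import normalize_and_augment

        x = np.stack([normalize_and_augment(p, self.normalizer) for p in patches])
        return self.encoder.features(x)


def embed(patches: np.ndarray, ids: pd.DataFrame, embedder) -> EmbeddingSet:
    """Deterministic embeddings for a stack of patches with provenance."""
    return EmbeddingSet(ids.reset_index(drop=True), np.asarray(embedder(patches), float),
                        getattr(embedder, "embedder_id", type(embedder).__name__))


# ---------------------------------------------------------------------------
# clustering


@dataclass
class ClusterModel:
    centroids: np.ndarray
    inertia: float
    fit_seed: int
    fit_sample_size: int

    @property
    def k(self) -> int:
        return len(self.centroids)


def fit_clusters(sample: np.ndarray, k: int, seed: int, n_init: int = 10) -> ClusterModel:
    """k-means (k-means++ init, ``n_init`` restarts, fixed seed) on a
    training-split embedding sample."""
    from sklearn.cluster import KMeans

    sample = np.asarray(sample, dtype=float)
    if len(sample) < k:
        raise ValueError(f"sample size {len(sample)} < k={k}")
    if len(np.unique(sample, axis=0)) < k:
        raise ValueError("fewer distinct points than clusters")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=int(seed) & 0x7FFFFFFF)
    km.fit(sample)
    return ClusterModel(km.cluster_centers_.copy(), float(km.inertia_), int(seed), len(sample))


def assign_clusters(model: ClusterModel, vectors: np.ndarray) -> np.ndarray:
    """Nearest-centroid assignment; exact ties resolve to the lowest index."""
    from scipy.spatial.distance import cdist

    d = cdist(np.asarray(vectors, float), model.centroids)
    return np.argmin(d, axis=1)  # argmin takes the first minimum on ties


def case_features(assignments: np.ndarray, case_ids, k: int, all_case_ids=None) -> pd.DataFrame:
    """Case x k matrix of tumor-patch percentages per cluster (rows sum to 100).

    Cases in ``all_case_ids`` without any tumor patch get a zero row and are
    flagged in ``result.attrs['zero_rows']``.
    """
    df = pd.DataFrame({"case_id": np.asarray(case_ids), "cluster": np.asarray(assignments)})
    counts = df.pivot_table(index="case_id", columns="cluster", aggfunc="size", fill_value=0)
    counts = counts.reindex(columns=range(k), fill_value=0)
    if all_case_ids is not None:
        counts = counts.reindex(list(all_case_ids), fill_value=0)
    totals = counts.sum(axis=1)
    out = counts.astype(float)
    nonzero = totals > 0
    out.loc[nonzero] = 100.0 * out.loc[nonzero].div(totals[nonzero], axis=0)
    out.columns = [f"cluster_{c}" for c in out.columns]
    out.attrs["zero_rows"] = list(totals.index[~nonzero])
    return out


# ---------------------------------------------------------------------------
# variance decomposition


@dataclass
class VarianceReport:
    params: pd.DataFrame  # coef, p per feature (+ intercept)
    r2: float
    adj_r2: float
    n: int
    selected_order: list | None = None
    dropped: list | None = None


def _ols_r2(X: np.ndarray, y: np.ndarray):
    """R^2 and adjusted R^2 of OLS with intercept (fast path for stepwise)."""
    n, p = X.shape
    Xc = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    resid = y - Xc @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n - p - 1 > 0 else -np.inf
    return r2, adj


def _drop_collinear(X: pd.DataFrame, tol: float = 1e-8):
    """Greedy rank filter: keep columns in order while they add rank."""
    keep, dropped = [], []
    M = np.ones((len(X), 1))
    for col in X.columns:
        v = X[col].to_numpy(float)
        cand = np.column_stack([M, v])
        if np.linalg.matrix_rank(cand, tol=tol * max(1.0, np.abs(cand).max())) > M.shape[1]:
            keep.append(col)
            M = cand
        else:
            dropped.append(col)
    return keep, dropped


def explain_variance(features: pd.DataFrame, scores: np.ndarray) -> VarianceReport:
    """OLS of standardized model scores on a feature matrix; reports
    coefficients, t-test p-values, R^2 and adjusted R^2."""
    import statsmodels.api as sm

    X = pd.DataFrame(features).copy()
    y = np.asarray(scores, dtype=float)
    if len(X) < X.shape[1] + 2:
        raise ValueError("need at least p + 2 rows")
    keep, dropped = _drop_collinear(X)
    if dropped:
        warnings.warn(f"dropping collinear features: {dropped}", stacklevel=2)
    X = X[keep]
    model = sm.OLS(y, sm.add_constant(X.to_numpy(float), has_constant="add")).fit()
    names = ["intercept"] + list(X.columns)
    params = pd.DataFrame({"coef": model.params, "p": model.pvalues}, index=names)
    return VarianceReport(params, float(model.rsquared), float(model.rsquared_adj),
                          len(X), dropped=dropped)


def clinicopath_regression(
    records: pd.DataFrame, scores: np.ndarray, covariates: dict | None = None
) -> VarianceReport:
    """Variance in standardized scores explained by clinicopathologic
    covariates (dummy coding, age centered and per-decade)."""
    from .evalmetrics import build_design

    X, _ = build_design(records, covariates)
    return explain_variance(X, scores)


def forward_stepwise(
    features: pd.DataFrame,
    scores: np.ndarray,
    n_select: int = 10,
    objective: str = "adjusted",
) -> VarianceReport:
    """Greedy forward selection: each step adds the feature maximizing the
    (adjusted, by default) R^2 of the refit model; ties resolve to the
    lowest feature index; exactly ``n_select`` steps, no early stopping."""
    X = pd.DataFrame(features)
    y = np.asarray(scores, dtype=float)
    if n_select > X.shape[1]:
        raise ValueError("n_select exceeds feature count")
    cols = list(X.columns)
    Xv = X.to_numpy(float)
    selected: list = []
    step_reports = []
    for _ in range(n_select):
        best = None
        for j, col in enumerate(cols):
            if col in selected:
                continue
            trial = [X.columns.get_loc(c) for c in selected] + [j]
            try:
                r2, adj = _ols_r2(Xv[:, trial], y)
            except np.linalg.LinAlgError:
                continue
            crit = adj if objective == "adjusted" else r2
            if best is None or crit > best[0] + 1e-12:
                best = (crit, col, r2, adj)
        if best is None:
            warnings.warn("degenerate fit; stopping with partial selection", stacklevel=2)
            break
        selected.append(best[1])
        step_reports.append({"feature": best[1], "r2": best[2], "adj_r2": best[3]})
    report = explain_variance(X[selected], y)
    report.selected_order = selected
    report.params.attrs["steps"] = step_reports
    return report


def select_k(
    train_sample: np.ndarray,
    tune_vectors: np.ndarray,
    tune_case_ids,
    tune_scores: pd.Series,
    ks=(10, 25, 50, 100, 200, 300, 400, 500),
    n_select: int = 10,
    seed: int = 0,
):
    """Choose the cluster count: for each candidate k, fit clusters on the
    training sample, build tune-split case features, run forward stepwise
    (up to ``n_select`` features) and keep the k with the best adjusted R^2
    (ties -> smaller k).  Returns ``(best_k, table)``."""
    results = []
    n_tune = len(tune_scores)
    for k in sorted(ks):
        if k > n_tune:
            continue
        model = fit_clusters(train_sample, k, seed)
        assign = assign_clusters(model, tune_vectors)
        feats = case_features(assign, tune_case_ids, k, all_case_ids=tune_scores.index)
        rep = forward_stepwise(feats, tune_scores.to_numpy(float), min(n_select, k))
        results.append({"k": k, "adj_r2": rep.adj_r2})
    if not results:
        raise ValueError("no candidate k fits the tune split")
    table = pd.DataFrame(results)
    best = int(table.loc[table["adj_r2"].idxmax(), "k"])  # idxmax -> first max, smaller k
    return best, table


# ---------------------------------------------------------------------------
# patch-level summaries


def patch_score_summary(
    patch_scores: np.ndarray,
    groups: np.ndarray,
    slide_ids: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-group mean, interquartile range and a 95% CI for the mean from a
    slide-level block bootstrap (slides resampled with replacement, all of a
    slide's patches move together).  Groups whose patches come from a single
    slide are flagged with a degenerate CI."""
    df = pd.DataFrame({
        "score": np.asarray(patch_scores, float),
        "group": np.asarray(groups),
        "slide": np.asarray(slide_ids),
    })
    rows = []
    for g, sub in df.groupby("group", sort=True):
        slides = sub["slide"].unique()
        rng = substream(seed, "block-boot", str(g))
        by_slide = {s: grp["score"].to_numpy() for s, grp in sub.groupby("slide")}
        means = []
        for _ in range(n_boot):
            pick = slides[rng.integers(0, len(slides), size=len(slides))]
            vals = np.concatenate([by_slide[s] for s in pick])
            means.append(vals.mean())
        lo, hi = np.percentile(means, [2.5, 97.5])
        q25, q75 = np.percentile(sub["score"], [25, 75])
        rows.append({
            "group": g,
            "n_patches": len(sub),
            "n_slides": len(slides),
            "mean": sub["score"].mean(),
            "iqr_low": q25,
            "iqr_high": q75,
            "ci_low": lo,
            "ci_high": hi,
            "single_slide": len(slides) == 1,
        })
    return pd.DataFrame(rows).set_index("group")


def single_feature_prognosis(
    feature_tune: pd.Series,
    feature_eval: pd.Series,
    eval_records: pd.DataFrame,
    horizon: int = 60,
    n_boot: int = 500,
    seed: int = 0,
) -> dict:
    """Evaluate one cluster-quantitation column as a standalone prognostic
    score: horizon AUC, quartile KM risk groups (thresholds from the tune
    split), and a univariable Cox hazard ratio per SD."""
    from . import evalmetrics as ev

    f_tune = feature_tune.to_numpy(float)
    f_eval = feature_eval.to_numpy(float)
    if len(np.unique(np.concatenate([f_tune, f_eval]))) < 2:
        raise ValueError("feature column is constant")
    out = {
        "five_year_auc": ev.five_year_auc(f_eval, eval_records, horizon, n_boot, seed),
    }
    try:
        out["km"] = ev.km_risk_groups(f_tune, f_eval, eval_records)
    except ValueError as err:  # e.g. mostly-zero feature collapses a group
        out["km_error"] = str(err)
    z = (f_eval - f_tune.mean()) / max(f_tune.std(), 1e-12)
    fit = ev.fit_cox(eval_records, covariates={}, X=pd.DataFrame({"feature": z},
                                                                 index=eval_records.index))
    out["cox"] = fit
    return out


def representative_patches(
    model: ClusterModel, embset: EmbeddingSet, cluster: int, m: int = 10
) -> pd.DataFrame:
    """The m patches nearest a cluster's centroid, at most one per case
    (distance ties -> smaller patch id)."""
    assign = assign_clusters(model, embset.vectors)
    member = np.flatnonzero(assign == cluster)
    if member.size == 0:
        raise ValueError(f"cluster {cluster} is empty")
    d = np.linalg.norm(embset.vectors[member] - model.centroids[cluster], axis=1)
    sub = embset.ids.iloc[member].copy()
    sub["distance"] = d
    sub = sub.sort_values(["distance", "patch_id"], kind="stable")
    picked = sub.drop_duplicates(subset="case_id", keep="first").head(m)
    if len(picked) < m:
        warnings.warn(
            f"only {len(picked)} distinct-case patches available for cluster {cluster}",
            stacklevel=2,
        )
    return picked.reset_index(drop=True)
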