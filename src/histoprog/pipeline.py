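"""End-to-end driver: simulate -> ROI masks -> train -> score -> evaluate ->
explain, with deterministic outputs and strict train/tune-only fitting.

Everything that is *fit* (probability threshold, color statistics, score
standardization constants, cluster centroids, the cluster count k, the
stepwise subset used for k-selection) derives from the train and tune
splits only; the validation splits are touched exclusively at evaluation
and report time.  The ids entering every fitting step are recorded in
``provenance.json`` so leakage is checkable after the fact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import evalmetrics as ev
from . import interpret as itp
from . import roimask as rm
from . import survmodel as sm
from .config import RunConfig
from .core import allocate_counts, substream
from .synthdata import SyntheticCohort, generate_cohort, true_heatmap

__all__ = ["split_cohort", "run_pipeline", "PipelineResult"]


def split_cohort(case_ids, ratios=(2, 1, 1), seed: int = 0, temporal_tags=None) -> pd.Series:
    """Case-level random split into train/tune/val1 (largest-remainder
    sizes), with cases tagged "late" assigned wholly to the temporal val2
    split first."""
    case_ids = list(case_ids)
    if len(case_ids) < len(ratios):
        raise ValueError("fewer cases than splits")
    tags = pd.Series("", index=case_ids) if temporal_tags is None else pd.Series(temporal_tags)
    out = pd.Series(index=case_ids, dtype=object, name="split")
    late = [c for c in case_ids if tags.get(c, "") == "late"]
    out.loc[late] = "val2"
    rest = [c for c in case_ids if c not in set(late)]
    rng = substream(seed, "split")
    order = rng.permutation(len(rest))
    counts = allocate_counts(len(rest), np.asarray(ratios, float))
    names = ["train", "tune", "val1"]
    pos = 0
    for name, cnt in zip(names, counts):
        for i in order[pos : pos + cnt]:
            out.loc[rest[i]] = name
        pos += cnt
    return out


@dataclass
class PipelineResult:
    outdir: pathlib.Path
    cohort: SyntheticCohort
    manifest: pd.DataFrame
    scores: pd.DataFrame
    metrics: dict
    provenance: dict


def _hash_config(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, pd.DataFrame):
        return x.to_dict(orient="index")
    if isinstance(x, pd.Series):
        return x.to_dict()
    if dataclasses.is_dataclass(x):
        return dataclasses.asdict(x)
    return str(x)


def run_pipeline(config: RunConfig, outdir, resume: bool = False) -> PipelineResult:
    """Run the full pipeline; identical config + seed give bit-identical
    reports.  With ``resume=True``, stages whose outputs already exist under
    a matching config hash are not rewritten."""
    config.validate()
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = _hash_config(config)
    stages_path = out / "stages.json"
    done = {}
    if resume and stages_path.exists():
        recorded = json.loads(stages_path.read_text())
        if recorded.get("config_hash") == chash:
            done = recorded.get("stages", {})

    def mark(stage):
        done[stage] = True
        _write_json(stages_path, {"config_hash": chash, "stages": done})

    def fresh(stage, *files):
        return done.get(stage) and all((out / f).exists() for f in files)

    provenance: dict = {}
    seed = config.seed

    # --- stage 1: simulate -------------------------------------------------
    cohort = generate_cohort(config.cohort, seed=seed)
    case_ids = [c.case_id for c in cohort.cases]
    tags = _temporal_tags(case_ids, config.val2_fraction, seed)
    split = split_cohort(case_ids, config.split_ratios, seed, temporal_tags=tags)
    manifest = cohort.records.copy()
    manifest["split"] = split.loc[manifest["case_id"]].to_numpy()
    if not fresh("simulate", "manifest.csv"):
        manifest.to_csv(out / "manifest.csv", index=False)
        config.to_json(out / "config_echo.json")
        mark("simulate")

    by_split = {s: manifest.loc[manifest["split"] == s, "case_id"].tolist()
                for s in ("train", "tune", "val1", "val2")}
    rec_ix = manifest.set_index("case_id")

    # --- stage 2: heatmaps + ROI masks + patch selection -------------------
    heat_rng = substream(seed, "heatmap-noise")
    heatmaps, labels = {}, {}
    for case in cohort.cases:
        for slide in case.slides:
            heatmaps[slide.slide_id] = true_heatmap(
                slide, cohort.config.heatmap_eps, config.roi.heatmap_noise, heat_rng
            )
            labels[slide.slide_id] = slide.tumor_superpixel_grid()
    tune_slides = [s.slide_id for cid in by_split["tune"] for s in cohort.case(cid).slides]
    threshold = rm.calibrate_threshold(
        [heatmaps[s] for s in tune_slides], [labels[s] for s in tune_slides],
        config.roi.target_recall,
    )
    provenance["threshold_calibration"] = sorted(by_split["tune"])
    selections = {}
    sel_rows = []
    for case in cohort.cases:
        for slide in case.slides:
            mask = rm.roi_mask(
                heatmaps[slide.slide_id], threshold, config.roi.radius,
                config.roi.min_component, config.roi.connectivity,
            )
            sel = rm.select_patches(mask, cohort.config.sp_per_patch)
            selections[slide.slide_id] = sel.coords()
            for _, row in sel.table.iterrows():
                sel_rows.append({"slide_id": slide.slide_id, "x": int(row.x),
                                 "y": int(row.y), "coverage": float(row.coverage)})
    if not fresh("roimask", "selections.csv"):
        pd.DataFrame(sel_rows).to_csv(out / "selections.csv", index=False)
        _write_json(out / "roi.json", {"threshold": threshold,
                                       "radius": config.roi.radius,
                                       "target_recall": config.roi.target_recall})
        mark("roimask")

    # --- stage 3: train ----------------------------------------------------
    sampler = sm.PatchSampler(cohort, selections)
    normalizer = sm.fit_normalizer(sampler, by_split["train"], seed)
    provenance["color_normalizer"] = sorted(by_split["train"])
    results = []
    for mi in range(config.n_models):
        model_seed = int(substream(seed, "model-seed", mi).integers(0, 2**31 - 1))
        res = sm.train(sampler, manifest, by_split["train"], by_split["tune"],
                       config.train, normalizer=normalizer, seed=model_seed)
        results.append(res)
    order = np.argsort([-r.best_c_index() for r in results], kind="stable")
    top = [results[i] for i in order[: config.train.ensemble_size]]
    if not fresh("train", "training_log.json"):
        _write_json(out / "training_log.json", {
            f"model_{i}": {"eval_steps": r.eval_steps, "c_index": r.c_index_series,
                           "mean_loss": float(np.mean(r.losses)) if r.losses else None,
                           "skipped_no_event_batches": r.skipped_batches}
            for i, r in enumerate(results)
        })
        mark("train")

    # --- stage 4: exhaustive scoring + ensembling --------------------------
    from .nn import SepConvEncoder

    scorable = [cid for cid in case_ids if sampler.index.get(cid)]
    encoders = []
    per_model_raw = []
    for res in top:
        enc = SepConvEncoder(config.train.encoder, substream(0, "shell"))
        enc.set_params(res.best_checkpoint())
        encoders.append(enc)
        per_model_raw.append(sm.score_cases(enc, sampler, scorable, normalizer))
    tune_ids = [c for c in by_split["tune"] if c in set(scorable)]
    tune_std, all_std = sm.ensemble_scores(
        [r.loc[tune_ids].to_numpy() for r in per_model_raw],
        [r.loc[scorable].to_numpy() for r in per_model_raw],
    )
    provenance["score_standardization"] = sorted(tune_ids)
    scores = pd.DataFrame({
        "case_id": scorable,
        "raw_score": np.mean([r.loc[scorable].to_numpy() for r in per_model_raw], axis=0),
        "standardized_score": all_std,
        "split": [split.loc[c] for c in scorable],
    })
    if not fresh("score", "scores.csv"):
        scores.to_csv(out / "scores.csv", index=False)
        mark("score")
    score_ix = scores.set_index("case_id")

    # --- stage 5: evaluate -------------------------------------------------
    metrics: dict = {
        "threshold": threshold,
        "n_cases": len(case_ids),
        "tune_best_c_index": float(max(r.best_c_index() for r in results)),
    }
    km_frames, hr_frames = [], []
    tune_scores_v = score_ix.loc[tune_ids, "standardized_score"].to_numpy()
    for vsplit in ("val1", "val2"):
        ids = [c for c in by_split[vsplit] if c in score_ix.index]
        if len(ids) < 10:
            continue
        recs = rec_ix.loc[ids].reset_index()
        s = score_ix.loc[ids, "standardized_score"].to_numpy()
        m = {
            "five_year_auc": ev.five_year_auc(s, recs, config.eval.horizon,
                                              config.eval.n_boot, seed),
            "c_index": ev.c_index(s, recs, config.eval.n_boot, seed),
        }
        try:
            uni = ev.fit_cox(recs, covariates={}, score=s,
                             reference_records=rec_ix.loc[tune_ids].reset_index(),
                             reference_score=tune_scores_v)
            m["cox_univariable"] = uni.summary.to_dict(orient="index")
        except (ValueError, RuntimeError) as err:
            m["cox_univariable_error"] = str(err)
        try:
            fit = ev.fit_cox(recs, score=s, reference_records=rec_ix.loc[tune_ids].reset_index(),
                             reference_score=tune_scores_v)
            m["cox_multivariable"] = fit.summary.to_dict(orient="index")
        except (ValueError, RuntimeError) as err:
            m["cox_multivariable_error"] = str(err)
        try:
            km = ev.km_risk_groups(tune_scores_v, s, recs)
            m["km_logrank_p_high_vs_low"] = km.logrank_p
            m["km_thresholds"] = km.thresholds
            for g, curve in km.km_curves.items():
                cf = curve.copy()
                cf.insert(0, "group", g)
                cf.insert(0, "split", vsplit)
                km_frames.append(cf)
            if km.hr_table is not None:
                hf = km.hr_table.reset_index(names="term")
                hf.insert(0, "split", vsplit)
                hr_frames.append(hf)
        except (ValueError, RuntimeError) as err:
            m["km_error"] = str(err)
        metrics[vsplit] = m
    if not fresh("evaluate", "metrics.json"):
        _write_json(out / "metrics.json", metrics)
        if km_frames:
            pd.concat(km_frames).to_csv(out / "km_curves.csv", index=False)
        if hr_frames:
            pd.concat(hr_frames).to_csv(out / "hr_table.csv", index=False)
        mark("evaluate")

    # --- stage 6: explain --------------------------------------------------
    explain_dir = out / "explain"
    explain_dir.mkdir(exist_ok=True)
    embedder = (itp.EncoderEmbedder(encoders[0], normalizer)
                if config.explain.embedder == "encoder" else itp.TextureStatEmbedder())
    ens = sm.EnsembleModel(encoders, normalizer, per_model_raw, tune_ids)

    def sample_embed(split_ids, n, tag):
        rng = substream(seed, "explain-sample", tag)
        entries, ids = [], []
        for cid in split_ids:
            for slide, r, c in sampler.index.get(cid, []):
                entries.append((slide, r, c))
                ids.append((cid, slide.slide_id, r, c))
        if not entries:
            raise ValueError(f"no ROI patches in split {tag}")
        pick = (np.arange(len(entries)) if len(entries) <= n
                else rng.choice(len(entries), size=n, replace=False))
        patches = sampler.render([entries[i] for i in pick])
        frame = pd.DataFrame([ids[i] for i in pick],
                             columns=["case_id", "slide_id", "row", "col"])
        frame.insert(0, "patch_id", np.asarray(pick, dtype=int))
        return patches, itp.embed(patches, frame, embedder)

    train_patches, train_emb = sample_embed(by_split["train"],
                                            config.explain.sample_patches, "train")
    _, tune_emb = sample_embed(tune_ids, config.explain.sample_patches, "tune")
    provenance["cluster_fit_sample"] = sorted(set(train_emb.ids["case_id"]))
    provenance["k_selection"] = sorted(tune_ids)

    tune_scores_series = pd.Series(tune_scores_v, index=tune_ids)
    best_k, k_table = itp.select_k(
        train_emb.vectors, tune_emb.vectors, tune_emb.ids["case_id"].to_numpy(),
        tune_scores_series, ks=config.explain.k_grid,
        n_select=config.explain.n_select, seed=seed,
    )
    cluster_model = itp.fit_clusters(train_emb.vectors, best_k, seed)

    def split_features(ids_list, tag):
        _, emb = sample_embed(ids_list, config.explain.patch_score_sample, f"feat-{tag}")
        assign = itp.assign_clusters(cluster_model, emb.vectors)
        feats = itp.case_features(assign, emb.ids["case_id"].to_numpy(), best_k,
                                  all_case_ids=ids_list)
        return feats, emb, assign

    val1_ids = [c for c in by_split["val1"] if c in score_ix.index]
    feats_val1, val1_emb, val1_assign = split_features(val1_ids, "val1")
    feats_tune, _, _ = split_features(tune_ids, "tune")
    s_val1 = score_ix.loc[val1_ids, "standardized_score"]

    rep_full = itp.explain_variance(feats_val1, s_val1.to_numpy())
    n_sel = min(config.explain.n_select, best_k)
    rep_step = itp.forward_stepwise(feats_val1, s_val1.to_numpy(), n_sel)
    recs_val1 = rec_ix.loc[val1_ids].reset_index()
    rep_clin = itp.clinicopath_regression(recs_val1, s_val1.to_numpy())

    # patch-level risk scores per cluster (singleton bags through the ensemble)
    val1_patch_scores = ens.patch_scores(
        sampler.render([(sampler_entry) for sampler_entry in _entries_for(val1_emb, sampler)])
    )
    summary = itp.patch_score_summary(
        val1_patch_scores, val1_assign, val1_emb.ids["slide_id"].to_numpy(),
        n_boot=config.explain.n_boot, seed=seed,
    )
    top_cluster = int(summary["mean"].idxmax())
    top_col = f"cluster_{top_cluster}"
    single = None
    try:
        single = itp.single_feature_prognosis(
            feats_tune[top_col], feats_val1[top_col], recs_val1,
            config.eval.horizon, config.explain.n_boot, seed,
        )
    except (ValueError, RuntimeError) as err:
        single = {"error": str(err)}

    if not fresh("explain", "explain/regressions.json"):
        k_table.to_csv(explain_dir / "k_selection.csv", index=False)
        feats_val1.to_csv(explain_dir / "feature_matrix_val1.csv")
        _write_json(explain_dir / "cluster_model.json", {
            "k": best_k, "centroids": cluster_model.centroids,
            "inertia": cluster_model.inertia, "embedder": train_emb.embedder_id,
        })
        _write_json(explain_dir / "regressions.json", {
            "cluster_full": {"r2": rep_full.r2, "adj_r2": rep_full.adj_r2},
            "cluster_stepwise": {"r2": rep_step.r2, "adj_r2": rep_step.adj_r2,
                                 "selected": rep_step.selected_order},
            "clinicopath": {"r2": rep_clin.r2, "adj_r2": rep_clin.adj_r2},
            "best_k": best_k,
        })
        rep_step.params.to_csv(explain_dir / "stepwise_coefficients.csv")
        rep_clin.params.to_csv(explain_dir / "clinicopath_coefficients.csv")
        summary.to_csv(explain_dir / "patch_score_summary.csv")
        _write_json(explain_dir / "single_feature.json", {
            "cluster": top_cluster,
            "five_year_auc": single.get("five_year_auc") if isinstance(single, dict) else None,
        })
        mark("explain")

    metrics["explain"] = {
        "best_k": best_k,
        "cluster_full_adj_r2": rep_full.adj_r2,
        "cluster_stepwise_adj_r2": rep_step.adj_r2,
        "clinicopath_adj_r2": rep_clin.adj_r2,
        "stepwise_selected": rep_step.selected_order,
        "top_patch_score_cluster": top_cluster,
        "single_feature": single,
    }
    if not fresh("provenance", "provenance.json"):
        _write_json(out / "provenance.json", provenance)
        mark("provenance")

    return PipelineResult(out, cohort, manifest, scores, metrics, provenance)


def _entries_for(embset, sampler):
    slide_by_id = {}
    for case in sampler.cohort.cases:
        for slide in case.slides:
            slide_by_id[slide.slide_id] = slide
    return [
        (slide_by_id[row.slide_id], int(row.row), int(row.col))
        for row in embset.ids.itertuples()
    ]


def _temporal_tags(case_ids, val2_fraction: float, seed: int) -> pd.Series:
    tags = pd.Series("", index=case_ids)
    if val2_fraction > 0:
        rng = substream(seed, "temporal")
        n_late = int(round(val2_fraction * len(case_ids)))
        late = rng.choice(len(case_ids), size=n_late, replace=False)
        tags.iloc[late] = "late"
    return tags
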