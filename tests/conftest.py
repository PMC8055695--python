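import numpy as np
import pytest

from histoprog import roimask as rm
from histoprog import survmodel as sm
from histoprog.config import EvalConfig, ExplainConfig, RunConfig
from histoprog.synthdata import CohortConfig, generate_cohort, true_heatmap


def tiny_run_config(seed=11):
    return RunConfig(
        cohort=CohortConfig(n_cases=80),
        train=sm.TrainConfig(steps=40, eval_every=20, eval_patches_per_case=16),
        n_models=1,
        eval=EvalConfig(n_boot=50),
        explain=ExplainConfig(sample_patches=500, k_grid=(3, 5),
                              patch_score_sample=500, n_boot=100),
        seed=seed,
    )


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory):
    """Two identical tiny end-to-end runs (for determinism and leakage checks)."""
    from histoprog.pipeline import run_pipeline

    root = tmp_path_factory.mktemp("pipe")
    cfg = tiny_run_config()
    res1 = run_pipeline(cfg, root / "a")
    res2 = run_pipeline(cfg, root / "b")
    return root, res1, res2


def build_selections(cohort, threshold=0.5, radius=1):
    """Noiseless ground-truth heatmaps -> ROI masks -> patch selections."""
    sel = {}
    for case in cohort.cases:
        for slide in case.slides:
            mask = rm.roi_mask(true_heatmap(slide, cohort.config.heatmap_eps),
                               threshold, radius)
            sel[slide.slide_id] = rm.select_patches(mask, cohort.config.sp_per_patch).coords()
    return sel


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortConfig(n_cases=60), seed=5)


@pytest.fixture(scope="session")
def small_sampler(small_cohort):
    return sm.PatchSampler(small_cohort, build_selections(small_cohort))


@pytest.fixture(scope="session")
def desk_run():
    """Desk-scale signal-recovery study: 400 cases (200 train / 100 tune /
    100 val), 300 training steps, plus a label-permuted null run under the
    same configuration and seeds.  Shared across the tests that probe
    signal recovery and explanation recovery."""
    cohort = generate_cohort(CohortConfig(n_cases=400), seed=101)
    ids = [c.case_id for c in cohort.cases]
    rng = np.random.default_rng(2024)
    order = rng.permutation(len(ids))
    train_ids = [ids[i] for i in order[:200]]
    tune_ids = [ids[i] for i in order[200:300]]
    val_ids = [ids[i] for i in order[300:]]
    sampler = sm.PatchSampler(cohort, build_selections(cohort))
    config = sm.TrainConfig(steps=300, eval_every=30, eval_patches_per_case=32)
    result = sm.train(sampler, cohort.records, train_ids, tune_ids, config, seed=77)

    permuted = cohort.records.copy()
    perm = np.random.default_rng(515).permutation(len(permuted))
    for col in ("time_months", "event", "censor_reason"):
        permuted[col] = permuted[col].to_numpy()[perm]
    null_result = sm.train(sampler, permuted, train_ids, tune_ids, config, seed=77)

    return {
        "cohort": cohort,
        "sampler": sampler,
        "splits": {"train": train_ids, "tune": tune_ids, "val": val_ids},
        "config": config,
        "result": result,
        "null_result": null_result,
    }
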