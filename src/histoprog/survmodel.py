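"""Weakly supervised prognostic model: bag-of-patches encoder + Cox head.

A case is a bag of image patches drawn from its tumor ROI across all slides.
The model scores each patch with a shared-weight encoder and linear Cox
head; the case-level risk score f(X_i) is the mean over the bag (mean
pooling commutes with the linear head, so the case score equals the mean of
per-patch scores and is exactly permutation invariant).

Training minimizes the negative log Cox partial likelihood over the cases
in each batch, with Breslow's approximation for tied event times: every
event contributes its score minus the log-sum-exp over its risk set
{j : T_j >= T_i}, and tied events share the same denominator.  Batches that
happen to contain no events carry no information about the partial
likelihood and are skipped (counted in the training log).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import standardize, substream, trailing_rolling_mean
from .nn import Adam, EncoderConfig, SepConvEncoder
from .synthdata import SyntheticCohort, render_slide_patch

__all__ = [
    "NoEventBatchError",
    "cox_partial_likelihood_loss",
    "ColorNormalizer",
    "normalize_and_augment",
    "TrainConfig",
    "PatchSampler",
    "train",
    "select_checkpoint",
    "ensemble_scores",
    "EnsembleModel",
    "score_case",
    "score_cases",
]


class NoEventBatchError(ValueError):
    """Raised when a batch contains no observed events (loss undefined)."""


def cox_partial_likelihood_loss(
    scores: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    return_grad: bool = False,
):
    """Negative log Cox partial likelihood with Breslow tie handling.

    loss = sum over events i of [ log(sum_{j: T_j >= T_i} e^{s_j}) - s_i ],
    with tied events sharing the same risk-set denominator.  Shift-invariant
    in the scores.  Returns the loss, or ``(loss, grad)`` with the analytic
    gradient w.r.t. the scores.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(times)
    e = np.asarray(events, dtype=bool)
    if s.shape != t.shape or s.shape != e.shape:
        raise ValueError("scores, times and events must have equal shapes")
    if not e.any():
        raise NoEventBatchError("batch contains no observed events")

    shift = s.max()
    w = np.exp(s - shift)
    loss = 0.0
    grad = np.zeros_like(s)
    for te in np.unique(t[e]):
        at_risk = t >= te
        tied = e & (t == te)
        d = int(tied.sum())
        denom = w[at_risk].sum()
        log_denom = np.log(denom) + shift
        loss += d * log_denom - s[tied].sum()
        if return_grad:
            grad[at_risk] += d * w[at_risk] / denom
            grad[tied] -= 1.0
    if return_grad:
        return float(loss), grad
    return float(loss)


# ---------------------------------------------------------------------------
# color normalization and augmentation


@dataclass
class ColorNormalizer:
    """Affine per-channel map taking training-set color statistics to a
    fixed reference distribution (mean 0.5, std 0.25 per channel on the
    [0, 1] scale).  One global map is fit on training patches and applied
    unchanged everywhere, so relative color differences between patches --
    which carry the texture classes' signal -- are preserved.
    """

    mean: np.ndarray = field(default_factory=lambda: np.full(3, 0.5))
    std: np.ndarray = field(default_factory=lambda: np.full(3, 0.25))
    ref_mean: float = 0.5
    ref_std: float = 0.25

    @classmethod
    def fit(cls, patches: np.ndarray) -> "ColorNormalizer":
        """Fit from a stack of uint8 patches (N, E, E, 3)."""
        x = np.asarray(patches, dtype=float) / 255.0
        return cls(mean=x.mean(axis=(0, 1, 2)), std=np.maximum(x.std(axis=(0, 1, 2)), 1e-6))

    def transform(self, patch: np.ndarray) -> np.ndarray:
        x = np.asarray(patch, dtype=float) / 255.0
        return (x - self.mean) * (self.ref_std / self.std) + self.ref_mean


def normalize_and_augment(
    patch: np.ndarray,
    normalizer: ColorNormalizer,
    rng: np.random.Generator | None = None,
    training: bool = False,
) -> np.ndarray:
    """Color-normalize one uint8 patch; in training mode also apply one of the
    8 dihedral orientations and bounded brightness/contrast/channel jitter.
    The evaluation path (``training=False``) is deterministic."""
    x = normalizer.transform(patch)
    if training:
        if rng is None:
            raise ValueError("training-mode augmentation requires an rng")
        k = int(rng.integers(8))
        x = np.rot90(x, k % 4, axes=(0, 1))
        if k >= 4:
            x = x[:, ::-1, :]
        x = x + rng.uniform(-0.08, 0.08)  # brightness
        x = (x - x.mean()) * rng.uniform(0.92, 1.08) + x.mean()  # contrast
        x = x * rng.uniform(0.96, 1.04, size=3)  # hue-like channel jitter
    return x - 0.5  # center for the encoder


# ---------------------------------------------------------------------------
# training configuration and data access


@dataclass
class TrainConfig:
    """Desk-scale defaults; the full-scale settings (2M steps, eval every
    10k, 1024 eval patches) remain expressible through the same fields."""

    n_patches_per_bag: int = 16
    eval_patches_per_case: int = 32
    batch_size: int = 32
    learning_rate: float = 3e-3
    steps: int = 600
    eval_every: int = 60
    rolling_window: int = 10
    ensemble_size: int = 5
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_patches_per_bag", "eval_patches_per_case", "batch_size",
                     "steps", "eval_every", "rolling_window", "ensemble_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.eval_every > self.steps:
            raise ValueError("eval_every must not exceed steps")


class PatchSampler:
    """Bridges a synthetic cohort + per-slide patch selections to the model.

    ``selections`` maps slide_id -> list of (row, col) patch-grid coordinates
    eligible for prognostication (from the ROI mask).  Rendering happens on
    demand; evaluation samples are drawn once per case from a fixed
    substream so tune-set scoring is deterministic across training steps.
    """

    def __init__(self, cohort: SyntheticCohort, selections: dict, cache: bool = True):
        self.cohort = cohort
        self.classes = cohort.config.texture_classes
        self.index: dict[str, list] = {}
        self._cache: dict | None = {} if cache else None
        for case in cohort.cases:
            pool = []
            for slide in case.slides:
                for rc in selections.get(slide.slide_id, []):
                    pool.append((slide, int(rc[0]), int(rc[1])))
            self.index[case.case_id] = pool

    def case_ids_with_patches(self):
        return [cid for cid, pool in self.index.items() if pool]

    def render(self, entries) -> np.ndarray:
        if self._cache is None:
            return np.stack(
                [render_slide_patch(slide, r, c, self.classes) for slide, r, c in entries]
            )
        out = []
        for slide, r, c in entries:
            key = (slide.slide_id, r, c)
            img = self._cache.get(key)
            if img is None:
                img = render_slide_patch(slide, r, c, self.classes)
                self._cache[key] = img
            out.append(img)
        return np.stack(out)

    def sample_bag(self, case_id: str, n: int, rng: np.random.Generator) -> np.ndarray:
        pool = self.index[case_id]
        if not pool:
            raise ValueError(f"case {case_id} has no ROI patches")
        idx = rng.choice(len(pool), size=n, replace=len(pool) < n)
        return self.render([pool[i] for i in idx])

    def eval_patches(self, case_id: str, n: int, seed: int) -> np.ndarray:
        pool = self.index[case_id]
        if not pool:
            raise ValueError(f"case {case_id} has no ROI patches")
        rng = substream(seed, "eval-patches", case_id)
        if len(pool) <= n:
            idx = np.arange(len(pool))
        else:
            idx = rng.choice(len(pool), size=n, replace=False)
        return self.render([pool[i] for i in idx])

    def all_patches(self, case_id: str) -> np.ndarray:
        pool = self.index[case_id]
        if not pool:
            raise ValueError(f"no tumor ROI for case {case_id}")
        return self.render(pool)


def fit_normalizer(sampler: PatchSampler, train_ids, seed: int, n_sample: int = 256) -> ColorNormalizer:
    """Fit the color reference on a random sample of training-split patches."""
    rng = substream(seed, "color-stats")
    patches = []
    ids = [cid for cid in train_ids if sampler.index.get(cid)]
    for _ in range(n_sample):
        cid = ids[int(rng.integers(len(ids)))]
        pool = sampler.index[cid]
        slide, r, c = pool[int(rng.integers(len(pool)))]
        patches.append(render_slide_patch(slide, r, c, sampler.classes))
    return ColorNormalizer.fit(np.stack(patches))


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainResult:
    eval_steps: list
    c_index_series: list
    checkpoints: list  # parameter dicts, one per eval point
    losses: list
    skipped_batches: int
    config: TrainConfig

    def best_checkpoint(self) -> dict:
        return self.checkpoints[select_checkpoint(self.c_index_series, self.config.rolling_window)]

    def best_c_index(self) -> float:
        i = select_checkpoint(self.c_index_series, self.config.rolling_window)
        return self.c_index_series[i]


def _case_scores(encoder: SepConvEncoder, patches_by_case, normalizer) -> np.ndarray:
    out = np.empty(len(patches_by_case))
    for i, patches in enumerate(patches_by_case):
        x = np.stack([normalize_and_augment(p, normalizer) for p in patches])
        out[i] = float(encoder.patch_scores(x).mean())
    return out


def _c_index_fast(scores, times, events) -> float:
    from .evalmetrics import c_index_value

    return c_index_value(scores, times, events)


def train(
    sampler: PatchSampler,
    records: pd.DataFrame,
    train_ids,
    tune_ids,
    config: TrainConfig,
    normalizer: ColorNormalizer | None = None,
    seed: int | None = None,
) -> TrainResult:
    """Train one prognostic model; returns the checkpoint series with the
    tune-set c-index at every evaluation point.

    The per-step loss is the batch approximation of the partial likelihood:
    risk sets are formed within the sampled batch of cases only.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rec = records.set_index("case_id")
    train_ids = [c for c in train_ids if sampler.index.get(c)]
    tune_ids = [c for c in tune_ids if sampler.index.get(c)]
    if rec.loc[tune_ids, "event"].sum() < 2:
        raise ValueError("tune split needs at least 2 events for a c-index")
    if normalizer is None:
        normalizer = fit_normalizer(sampler, train_ids, seed)

    rng = substream(seed, "train-loop")
    encoder = SepConvEncoder(config.encoder, substream(seed, "init"))
    opt = Adam(lr=config.learning_rate)

    # deterministic tune-eval cache (uint8 to keep memory small)
    tune_cache = [sampler.eval_patches(cid, config.eval_patches_per_case, seed) for cid in tune_ids]
    tune_t = rec.loc[tune_ids, "time_months"].to_numpy()
    tune_e = rec.loc[tune_ids, "event"].to_numpy(dtype=bool)

    times_all = rec["time_months"]
    events_all = rec["event"]

    eval_steps, c_series, checkpoints, losses = [], [], [], []
    skipped = 0
    n_bag = config.n_patches_per_bag
    for step in range(1, config.steps + 1):
        bsize = min(config.batch_size, len(train_ids))
        batch = [train_ids[i] for i in rng.choice(len(train_ids), size=bsize, replace=False)]
        ev = events_all.loc[batch].to_numpy(dtype=bool)
        if not ev.any():
            skipped += 1
            continue
        tt = times_all.loc[batch].to_numpy()

        bags = np.concatenate([
            np.stack([
                normalize_and_augment(p, normalizer, rng, training=True)
                for p in sampler.sample_bag(cid, n_bag, rng)
            ])
            for cid in batch
        ])
        feats, cache = encoder.features(bags, want_cache=True)
        patch_scores = encoder.head(feats)
        case_scores = patch_scores.reshape(bsize, n_bag).mean(axis=1)
        loss, dcase = cox_partial_likelihood_loss(case_scores, tt, ev, return_grad=True)
        losses.append(loss / max(int(ev.sum()), 1))
        dpatch = np.repeat(dcase / n_bag, n_bag)
        grads = encoder.backward(dpatch, feats, cache)
        opt.step(encoder.params, grads)

        if step % config.eval_every == 0:
            tune_scores = _case_scores(encoder, tune_cache, normalizer)
            c = _c_index_fast(tune_scores, tune_t, tune_e)
            eval_steps.append(step)
            c_series.append(c)
            checkpoints.append(encoder.get_params())

    return TrainResult(eval_steps, c_series, checkpoints, losses, skipped, config)


def select_checkpoint(c_index_series, window: int = 10) -> int:
    """Index of the checkpoint maximizing the trailing rolling-mean c-index
    (window shrinks at the start; ties resolve to the earliest step)."""
    series = np.asarray(c_index_series, dtype=float)
    if series.size == 0:
        raise ValueError("empty checkpoint series")
    smoothed = trailing_rolling_mean(series, window)
    return int(np.argmax(smoothed))  # argmax returns the first maximum


# ---------------------------------------------------------------------------
# ensembling and scoring


def ensemble_scores(per_model_tune: list, per_model_eval: list):
    """Combine models: standardize each model's scores on the tune split,
    average, then re-standardize the ensemble on tune.

    Returns ``(tune_scores, eval_scores)`` as standardized arrays.
    """
    if len(per_model_tune) == 0 or len(per_model_tune) != len(per_model_eval):
        raise ValueError("need matching, non-empty per-model score lists")
    zt, ze = [], []
    for t_raw, e_raw in zip(per_model_tune, per_model_eval):
        z, mu, sd = standardize(np.asarray(t_raw, float))
        zt.append(z)
        ze.append((np.asarray(e_raw, float) - mu) / sd)
    mt = np.mean(zt, axis=0)
    me = np.mean(ze, axis=0)
    out_t, mu2, sd2 = standardize(mt)
    return out_t, (me - mu2) / sd2


class EnsembleModel:
    """Frozen ensemble: per-model standardization on the tune split, mean,
    re-standardization on tune.  Because every transform is affine and the
    head is linear, a case's ensemble score equals the mean of its patches'
    ensemble patch-level scores, so patch-level risk decomposition is
    consistent with case-level scoring."""

    def __init__(self, encoders, normalizer: ColorNormalizer, per_model_raw, tune_ids):
        if len(encoders) == 0 or len(encoders) != len(per_model_raw):
            raise ValueError("need one raw-score series per encoder")
        self.encoders = encoders
        self.normalizer = normalizer
        self.model_stats = []
        zt = []
        for raw in per_model_raw:
            z, mu, sd = standardize(raw.loc[tune_ids].to_numpy(float))
            self.model_stats.append((mu, sd))
            zt.append(z)
        _, self.final_mu, self.final_sd = standardize(np.mean(zt, axis=0))

    def patch_scores(self, patches: np.ndarray, chunk: int = 512) -> np.ndarray:
        """Standardized ensemble scores for singleton bags (uint8 patches)."""
        out = np.zeros(len(patches))
        for lo in range(0, len(patches), chunk):
            x = np.stack([
                normalize_and_augment(p, self.normalizer) for p in patches[lo : lo + chunk]
            ])
            zs = [
                (enc.patch_scores(x) - mu) / sd
                for enc, (mu, sd) in zip(self.encoders, self.model_stats)
            ]
            out[lo : lo + chunk] = (np.mean(zs, axis=0) - self.final_mu) / self.final_sd
        return out


def score_case(
    encoder: SepConvEncoder,
    sampler: PatchSampler,
    case_id: str,
    normalizer: ColorNormalizer,
    chunk: int = 256,
) -> float:
    """Exhaustive, deterministic case score: the mean patch score over every
    selected ROI patch of every slide, computed in chunks."""
    patches = sampler.all_patches(case_id)
    total, n = 0.0, 0
    for lo in range(0, len(patches), chunk):
        x = np.stack([normalize_and_augment(p, normalizer) for p in patches[lo : lo + chunk]])
        s = encoder.patch_scores(x)
        total += float(s.sum())
        n += len(s)
    return total / n


def score_cases(encoder, sampler, case_ids, normalizer, chunk: int = 256) -> pd.Series:
    return pd.Series(
        {cid: score_case(encoder, sampler, cid, normalizer, chunk) for cid in case_ids},
        name="raw_score",
    )
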