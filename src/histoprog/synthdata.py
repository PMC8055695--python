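"""Synthetic cohorts with planted, texture-defined prognostic features.

Every downstream stage (ROI masking, weakly supervised training, survival
evaluation, cluster-based explanation) is exercised against cohorts produced
here, where the ground truth is known by construction:

* each slide is a grid of fixed-size RGB patches, each patch carrying exactly
  one procedural texture class (tumor or non-tumor);
* per case, the proportions ``z`` of its tumor patches across tumor classes
  drive a proportional-hazards survival model with log-hazard
  ``eta = sum_c hazard_weight_c * z_c``;
* survival times are exponential with rate ``h0 * exp(eta)``, discretized to
  whole months by ceiling, and right-censored by the earlier of an
  administrative horizon and an independent non-disease censoring time.

The generator emulates the structure of a two-stage colorectal resection
cohort (multi-slide cases, ~37% disease-specific event rate, both disease
and non-disease censoring) without claiming any visual realism: textures are
Gaussian-blob / oriented-stripe patterns over a base color, separable by
low-order color statistics by design.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from .core import (
    CENSOR_ADMIN,
    CENSOR_DISEASE,
    CENSOR_NONDISEASE,
    allocate_counts,
    substream,
    validate_records,
)

__all__ = [
    "TextureClass",
    "CohortConfig",
    "SyntheticSlide",
    "SyntheticCase",
    "SyntheticCohort",
    "default_texture_classes",
    "generate_cohort",
    "render_patch",
    "true_heatmap",
]


@dataclass(frozen=True)
class TextureClass:
    """A procedural texture with a per-unit-proportion log-hazard contribution."""

    class_id: int
    base_rgb: tuple
    blob_density: float  # expected dark blobs per 32x32 px
    stripe_freq: float  # stripe cycles across one patch (0 = none)
    stripe_angle: float = 0.0  # radians
    hazard_weight: float = 0.0
    is_tumor: bool = False
    planted: bool = False  # the designated high-risk class


def default_texture_classes() -> tuple:
    """Two non-tumor and three tumor classes; class 4 is the planted high-risk one.

    The planted class plays the role of a morphologically distinct high-risk
    histologic pattern (e.g. poorly differentiated tumor adjacent to adipose
    tissue): it is visually separable and carries the dominant hazard weight.
    """
    return (
        TextureClass(0, (228, 190, 208), 1.0, 0.0, 0.0, 0.0, False),  # stroma-like
        TextureClass(1, (242, 236, 239), 0.3, 0.0, 0.0, 0.0, False),  # adipose-like
        TextureClass(2, (168, 122, 186), 2.0, 0.0, 0.0, 0.0, True),   # tumor, low risk
        TextureClass(3, (128, 92, 158), 1.0, 6.0, 0.6, 1.5, True),    # tumor, mid risk
        TextureClass(4, (94, 62, 124), 4.0, 12.0, 2.2, 8.0, True, True),  # planted
    )


@dataclass
class CohortConfig:
    """Generation conditions for a synthetic cohort.

    Defaults are the desk-scale study conditions: 400 cases, two slides per
    case, 8x8 patches of 64 px per slide, 4 heatmap superpixels per patch
    edge, a 37% disease-specific event-rate target, a 120-month
    administrative horizon and independent non-disease censoring tuned so
    ~10% of cases are censored before 60 months.
    """

    n_cases: int = 400
    slides_per_case: int = 2
    patch_grid: tuple = (8, 8)  # patches per slide (rows, cols)
    sp_per_patch: int = 4  # heatmap superpixels per patch edge
    patch_edge_px: int = 64
    texture_classes: tuple = field(default_factory=default_texture_classes)
    tumor_fraction_range: tuple = (0.4, 0.75)
    planted_range: tuple = (0.0, 0.5)  # case-level planted-class proportion
    dirichlet_alpha: float = 2.0  # over the remaining tumor classes
    baseline_hazard: float | None = None  # per month; solved if None
    event_rate_target: float | None = 0.37
    admin_horizon_months: int = 120
    nondisease_censor_rate: float = -float(np.log(0.9)) / 60.0  # ~10% by 5 years
    heatmap_eps: float = 0.02
    seed: int = 0

    def tumor_classes(self):
        return [t for t in self.texture_classes if t.is_tumor]

    def validate(self) -> None:
        if self.n_cases < 2:
            raise ValueError("n_cases must be >= 2")
        ids = [t.class_id for t in self.texture_classes]
        if len(set(ids)) != len(ids):
            raise ValueError("texture class_ids must be unique")
        if not self.tumor_classes():
            raise ValueError("at least one tumor texture class is required")
        if sum(t.planted for t in self.texture_classes) > 1:
            raise ValueError("at most one planted high-risk class is allowed")
        for t in self.texture_classes:
            if not t.is_tumor and t.hazard_weight != 0:
                raise ValueError("non-tumor classes must have hazard_weight = 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["texture_classes"] = [dataclasses.asdict(t) for t in self.texture_classes]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = {k: v for k, v in d.items() if k in {f.name for f in dataclasses.fields(cls)}}
        if "texture_classes" in d:
            d["texture_classes"] = tuple(
                TextureClass(**{**t, "base_rgb": tuple(t["base_rgb"])})
                for t in d["texture_classes"]
            )
        for key in ("patch_grid", "tumor_fraction_range", "planted_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticSlide:
    slide_id: str
    class_grid: np.ndarray  # (rows, cols) int patch-level ground-truth class ids
    sp_per_patch: int
    patch_edge_px: int
    render_seed: int

    @property
    def tumor_patch_mask(self) -> np.ndarray:
        return np.isin(self.class_grid, self._tumor_ids)

    def set_tumor_ids(self, tumor_ids) -> None:
        self._tumor_ids = np.asarray(sorted(tumor_ids))

    def tumor_superpixel_grid(self) -> np.ndarray:
        """Boolean superpixel grid: tumor patches expand to their footprint."""
        return np.kron(self.tumor_patch_mask, np.ones((self.sp_per_patch,) * 2, bool))

    def superpixel_label_grid(self) -> np.ndarray:
        return np.kron(self.class_grid, np.ones((self.sp_per_patch,) * 2, int))


@dataclass
class SyntheticCase:
    case_id: str
    slides: list
    z: dict  # tumor class id -> true case-level proportion (sums to 1)
    eta: float  # true log hazard


@dataclass
class SyntheticCohort:
    cases: list
    records: pd.DataFrame
    config_echo: dict
    #: latent draws underlying the observed outcomes (case_id, event_time,
    #: censor_time in continuous months) -- useful for independence checks
    latents: pd.DataFrame | None = None

    @property
    def config(self) -> CohortConfig:
        return CohortConfig.from_dict(self.config_echo)

    def case(self, case_id: str) -> SyntheticCase:
        return self._by_id[case_id]

    def index_cases(self) -> None:
        self._by_id = {c.case_id: c for c in self.cases}

    def true_eta(self) -> pd.Series:
        return pd.Series({c.case_id: c.eta for c in self.cases}, name="eta")


# ---------------------------------------------------------------------------
# patch rendering


def render_patch(texture: TextureClass, coords, seed: int, edge: int = 64) -> np.ndarray:
    """Render one RGB patch (uint8, edge x edge x 3), deterministic in its inputs.

    ``coords`` is any tuple of small non-negative integers identifying the
    patch (e.g. slide render seed plus grid position).
    """
    key = [int(seed) & 0x7FFFFFFF, int(texture.class_id)] + [int(c) & 0x7FFFFFFF for c in coords]
    rng = np.random.default_rng(np.random.SeedSequence(key))
    img = np.empty((edge, edge, 3), dtype=float)
    img[:] = np.asarray(texture.base_rgb, dtype=float)
    img += rng.normal(0.0, 6.0, size=(edge, edge, 3))

    yy, xx = np.mgrid[0:edge, 0:edge].astype(float)
    n_blobs = int(rng.poisson(texture.blob_density * (edge / 32.0) ** 2))
    if n_blobs > 0:
        cy = rng.uniform(0, edge, size=n_blobs)[:, None, None]
        cx = rng.uniform(0, edge, size=n_blobs)[:, None, None]
        sig = rng.uniform(1.5, edge / 10.0, size=n_blobs)[:, None, None]
        amp = rng.uniform(25.0, 60.0, size=n_blobs)[:, None, None]
        bumps = amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig**2))
        img -= bumps.sum(axis=0)[..., None]

    if texture.stripe_freq > 0:
        phase = rng.uniform(0, 2 * np.pi)
        u = xx * np.cos(texture.stripe_angle) + yy * np.sin(texture.stripe_angle)
        stripes = 14.0 * np.sin(2 * np.pi * texture.stripe_freq * u / edge + phase)
        img += stripes[..., None]

    return np.clip(img, 0, 255).astype(np.uint8)


def render_slide_patch(slide: SyntheticSlide, row: int, col: int, classes) -> np.ndarray:
    """Render the patch at grid position (row, col) of a synthetic slide."""
    cid = int(slide.class_grid[row, col])
    texture = next(t for t in classes if t.class_id == cid)
    return render_patch(texture, (row, col), slide.render_seed, slide.patch_edge_px)


# ---------------------------------------------------------------------------
# heatmaps


def true_heatmap(
    slide: SyntheticSlide,
    eps: float = 0.02,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Ground-truth tumor-probability heatmap at superpixel resolution.

    Bypasses a learned tumor classifier: tumor superpixels get probability
    ``1 - eps``, others ``eps``; optional i.i.d. Gaussian noise (clipped to
    [0, 1]) supports threshold-calibration tests.
    """
    grid = np.where(slide.tumor_superpixel_grid(), 1.0 - eps, eps)
    if noise_sigma > 0:
        if rng is None:
            raise ValueError("noise requires an explicit rng")
        grid = np.clip(grid + rng.normal(0.0, noise_sigma, grid.shape), 0.0, 1.0)
    return grid


# ---------------------------------------------------------------------------
# survival model


def _expected_event_fraction(log_h0: float, eta: np.ndarray, cfg: CohortConfig) -> float:
    lam = np.exp(log_h0 + eta)
    lc = cfg.nondisease_censor_rate
    H = cfg.admin_horizon_months
    tot = lam + lc
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(tot > 0, lam / np.maximum(tot, 1e-300) * (1 - np.exp(-tot * H)), 0.0)
    return float(p.mean())


def _solve_baseline_hazard(eta: np.ndarray, cfg: CohortConfig) -> float:
    """Solve h0 so the expected event fraction hits the configured target."""
    target = cfg.event_rate_target
    if not 0 < target < 1:
        raise ValueError("event-rate target must lie strictly in (0, 1)")
    lo, hi = -16.0, 8.0
    f = lambda x: _expected_event_fraction(x, eta, cfg) - target
    if f(hi) < 0 or f(lo) > 0:
        raise ValueError(
            f"event-rate target {target} unreachable under the censoring model "
            f"(admin horizon {cfg.admin_horizon_months} mo, non-disease rate "
            f"{cfg.nondisease_censor_rate:.5f}/mo)"
        )
    return float(np.exp(brentq(f, lo, hi, xtol=1e-12)))


def _draw_survival(eta: np.ndarray, h0: float, cfg: CohortConfig, rng: np.random.Generator):
    lam = h0 * np.exp(eta)
    t_event = rng.exponential(1.0 / lam)
    t_censor = rng.exponential(1.0 / cfg.nondisease_censor_rate, size=len(eta))
    H = float(cfg.admin_horizon_months)
    t_obs = np.minimum(np.minimum(t_event, t_censor), H)
    event = t_event <= np.minimum(t_censor, H)
    reason = np.where(
        event, CENSOR_DISEASE, np.where(t_censor < H, CENSOR_NONDISEASE, CENSOR_ADMIN)
    )
    months = np.maximum(np.ceil(t_obs).astype(int), 1)
    return months, event, reason, t_event, t_censor


# ---------------------------------------------------------------------------
# spatial layout


def _smooth_field(shape, rng: np.random.Generator, sigma: float = 1.2) -> np.ndarray:
    return gaussian_filter(rng.normal(size=shape), sigma, mode="wrap")


def _layout_slide(cfg: CohortConfig, z_target: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Patch-level class grid for one slide with spatially coherent regions."""
    tumor = cfg.tumor_classes()
    nontumor = [t for t in cfg.texture_classes if not t.is_tumor]
    shape = cfg.patch_grid
    frac = rng.uniform(*cfg.tumor_fraction_range)
    tumor_field = _smooth_field(shape, rng)
    thr = np.quantile(tumor_field, 1 - frac)
    tumor_mask = tumor_field >= thr

    grid = np.full(shape, -1, dtype=int)
    class_field = _smooth_field(shape, rng, sigma=1.0)

    def fill(mask, classes, weights):
        idx = np.flatnonzero(mask.ravel())
        if len(idx) == 0:
            return
        order = idx[np.argsort(class_field.ravel()[idx], kind="stable")]
        counts = allocate_counts(len(idx), np.asarray(weights))
        flat = grid.ravel()
        pos = 0
        for t, c in zip(classes, counts):
            flat[order[pos : pos + c]] = t.class_id
            pos += c
        grid.ravel()[:] = flat

    fill(tumor_mask, tumor, z_target)
    if nontumor:
        nt_weights = np.array([1.0 if t.class_id == 0 else 0.5 for t in nontumor])
        fill(~tumor_mask, nontumor, nt_weights)
    else:  # degenerate config: everything tumor
        fill(~tumor_mask, tumor, z_target)
    return grid


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(config: CohortConfig, seed: int | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort; identical config + seed => identical cohort.

    ``seed`` overrides ``config.seed`` when given.
    """
    config = dataclasses.replace(config, seed=int(config.seed if seed is None else seed))
    config.validate()
    tumor = config.tumor_classes()
    tumor_ids = [t.class_id for t in tumor]
    planted = [t for t in tumor if t.planted]

    layout_rng = substream(config.seed, "synthdata", "layout")
    surv_rng = substream(config.seed, "synthdata", "survival")
    cov_rng = substream(config.seed, "synthdata", "covariates")

    cases = []
    etas = np.empty(config.n_cases)
    weights = {t.class_id: t.hazard_weight for t in tumor}
    for i in range(config.n_cases):
        case_id = f"case_{i:05d}"
        # case-level target tumor-class mixture
        if planted and len(tumor) > 1:
            zp = layout_rng.uniform(*config.planted_range)
            rest = layout_rng.dirichlet([config.dirichlet_alpha] * (len(tumor) - 1))
            z_target = np.empty(len(tumor))
            for j, t in enumerate(tumor):
                z_target[j] = zp if t.planted else 0.0
            z_target[[not t.planted for t in tumor]] = (1 - zp) * rest
        else:
            z_target = layout_rng.dirichlet([config.dirichlet_alpha] * len(tumor))

        slides = []
        counts = np.zeros(len(tumor), dtype=int)
        for s in range(config.slides_per_case):
            grid = _layout_slide(config, z_target, layout_rng)
            render_seed = int(layout_rng.integers(0, 2**31 - 1))
            slide = SyntheticSlide(
                f"{case_id}_s{s}", grid, config.sp_per_patch, config.patch_edge_px, render_seed
            )
            slide.set_tumor_ids(tumor_ids)
            slides.append(slide)
            for j, t in enumerate(tumor):
                counts[j] += int((grid == t.class_id).sum())
        total = counts.sum()
        z = counts / total if total > 0 else np.full(len(tumor), 1.0 / len(tumor))
        eta = float(sum(weights[t.class_id] * z[j] for j, t in enumerate(tumor)))
        etas[i] = eta
        cases.append(SyntheticCase(case_id, slides, {t.class_id: float(z[j]) for j, t in enumerate(tumor)}, eta))

    h0 = config.baseline_hazard
    if h0 is None:
        if config.event_rate_target is None:
            raise ValueError("either baseline_hazard or event_rate_target must be set")
        h0 = _solve_baseline_hazard(etas, config)
    months, event, reason, t_event, t_censor = _draw_survival(etas, h0, config, surv_rng)

    planted_ids = {t.class_id for t in planted}
    records = _draw_covariates(cases, planted_ids, cov_rng)
    records["time_months"] = months
    records["event"] = event
    records["censor_reason"] = reason
    validate_records(records)

    echo = config.to_dict()
    echo["solved_baseline_hazard"] = float(h0)
    latents = pd.DataFrame({"case_id": [c.case_id for c in cases],
                            "event_time": t_event, "censor_time": t_censor})
    cohort = SyntheticCohort(cases=cases, records=records, config_echo=echo,
                             latents=latents)
    cohort.index_cases()
    return cohort


def _draw_covariates(cases, planted_ids, rng: np.random.Generator) -> pd.DataFrame:
    """Clinicopathologic-style covariates, mildly linked to the planted proportion.

    N and T categories are tilted by the planted-class proportion so that the
    clinicopathologic regression explains a small, nonzero share of variance
    in model scores (a qualitative analog of stage capturing part of risk).
    """
    rows = []
    for c in cases:
        planted_z = sum(z for cid, z in c.z.items() if cid in planted_ids)
        p_npos = min(0.85, 0.35 + 0.5 * planted_z)
        npos = rng.random() < p_npos
        n_cat = rng.choice(["N1", "N2", "N3"], p=[0.6, 0.3, 0.1]) if npos else "N0"
        t_cat = "T4" if rng.random() < min(0.8, 0.2 + 0.6 * planted_z) else "T3"
        rows.append(
            dict(
                case_id=c.case_id,
                stage="III" if npos else "II",
                age=float(np.clip(rng.normal(68, 11), 30, 95)),
                sex=rng.choice(["male", "female"]),
                grade=rng.choice(["G1", "G2", "G3"], p=[0.2, 0.55, 0.25]),
                t_cat=t_cat,
                n_cat=n_cat,
                r_cat=rng.choice(["R0", "R1"], p=[0.92, 0.08]),
                l_cat=rng.choice(["L0", "L1"], p=[0.7, 0.3]),
                v_cat=rng.choice(["V0", "V1"], p=[0.85, 0.15]),
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# on-disk export (plain formats only)


def write_cohort(cohort: SyntheticCohort, outdir, write_images: bool = False) -> None:
    """Write manifest CSV, config echo JSON and (optionally) patch PNGs / TIFFs."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for c in cohort.cases:
        for s in c.slides:
            rec = cohort.records.set_index("case_id").loc[c.case_id]
            rows.append({"case_id": c.case_id, "slide_id": s.slide_id, **rec.to_dict()})
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    with open(out / "config_echo.json", "w") as fh:
        json.dump(cohort.config_echo, fh, indent=2, sort_keys=True)
    if write_images:
        from PIL import Image
        import tifffile

        classes = cohort.config.texture_classes
        for c in cohort.cases:
            for s in c.slides:
                sdir = out / "slides" / s.slide_id
                sdir.mkdir(parents=True, exist_ok=True)
                rows_, cols_ = s.class_grid.shape
                for r in range(rows_):
                    for q in range(cols_):
                        img = render_slide_patch(s, r, q, classes)
                        Image.fromarray(img).save(sdir / f"patch_y{r:03d}_x{q:03d}.png")
                tifffile.imwrite(
                    out / "slides" / f"{s.slide_id}_heatmap.tif",
                    true_heatmap(s, cohort.config.heatmap_eps).astype(np.float32),
                )
                tifffile.imwrite(
                    out / "slides" / f"{s.slide_id}_labels.tif",
                    s.superpixel_label_grid().astype(np.uint8),
                )
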