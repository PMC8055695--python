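"""Survival evaluation: horizon AUC with the censoring exclusion rule,
Harrell's c-index, Breslow Cox regression with the study's covariate
codings, and quartile-threshold Kaplan-Meier risk groups.

Conventions (declared once, used everywhere):

* 5-year AUC: positives are disease events at <= 60 months (boundary month
  inclusive); cases censored for non-disease reasons before the horizon are
  excluded as uninformative; everyone else followed to the horizon is a
  negative.  The AUC is the rank statistic with score ties counted 1/2.
* c-index: a pair is admissible iff the strictly earlier time is an
  observed event; score ties count 1/2.
* Cox fits maximize the Breslow partial likelihood by Newton's method.
  Codings: model scores standardized to zero mean / unit variance on a
  stated reference split, age centered and divided by 10 (hazard ratio per
  decade), all other covariates dummy-coded against declared reference
  levels.  Times are whole months.
* Risk groups: low = score <= 25th percentile of the tune scores, high =
  score >= 75th percentile (linear-interpolation percentiles), medium
  between; the log-rank test compares high vs. low only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CENSOR_DISEASE, standardize, substream, validate_records

__all__ = [
    "five_year_auc",
    "horizon_classes",
    "c_index",
    "c_index_value",
    "CoxFitResult",
    "fit_cox",
    "build_design",
    "RiskGroups",
    "km_risk_groups",
    "added_value_report",
    "DEFAULT_COVARIATES",
]

#: covariate -> reference level, mirroring the study's multivariable model
DEFAULT_COVARIATES = {
    "sex": "male",
    "grade": "G1",
    "l_cat": "L0",
    "n_cat": "N0",
    "r_cat": "R0",
    "t_cat": "T3",
    "v_cat": "V0",
}


# ---------------------------------------------------------------------------
# 5-year AUC with exclusion rule


def horizon_classes(records: pd.DataFrame, horizon: int = 60):
    """Classify cases for horizon-AUC: returns (positive, negative, excluded)
    boolean arrays.  Excluded = censored before the horizon for a
    non-disease reason (uninformative for the horizon outcome)."""
    validate_records(records)
    t = records["time_months"].to_numpy()
    e = records["event"].to_numpy(dtype=bool)
    pos = e & (t <= horizon)
    excluded = ~e & (t < horizon)
    neg = ~pos & ~excluded
    return pos, neg, excluded


def five_year_auc(
    scores: np.ndarray,
    records: pd.DataFrame,
    horizon: int = 60,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Horizon (default 5-year) AUC for disease-specific survival.

    Returns a dict with the AUC, a case-level bootstrap CI, and the
    inclusion/exclusion accounting.
    """
    from sklearn.metrics import roc_auc_score

    scores = np.asarray(scores, dtype=float)
    pos, neg, excl = horizon_classes(records, horizon)
    if pos.sum() == 0 or neg.sum() == 0:
        raise ValueError(
            f"degenerate horizon classes after exclusion: {int(pos.sum())} positives, "
            f"{int(neg.sum())} negatives ({int(excl.sum())} excluded)"
        )
    keep = pos | neg
    y = pos[keep].astype(int)
    s = scores[keep]
    auc = float(roc_auc_score(y, s))

    rng = substream(seed, "auc-boot")
    reps = []
    n = len(y)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if y[idx].min() == y[idx].max():
            continue
        reps.append(roc_auc_score(y[idx], s[idx]))
    lo, hi = (np.percentile(reps, [2.5, 97.5]) if reps else (np.nan, np.nan))
    return {
        "auc": auc,
        "ci": (float(lo), float(hi)),
        "n_included": int(keep.sum()),
        "n_excluded": int(excl.sum()),
        "n_pos": int(pos.sum()),
        "n_neg": int(neg.sum()),
    }


# ---------------------------------------------------------------------------
# concordance index


def c_index_value(scores, times, events) -> float:
    """Harrell's c over admissible pairs (vectorized O(n^2))."""
    s = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    adm = (t[:, None] < t[None, :]) & e[:, None]
    n_adm = adm.sum()
    if n_adm == 0:
        raise ValueError("no admissible pairs for the c-index")
    conc = (s[:, None] > s[None, :]) & adm
    tied = (s[:, None] == s[None, :]) & adm
    return float((conc.sum() + 0.5 * tied.sum()) / n_adm)


def c_index(scores, records: pd.DataFrame, n_boot: int = 1000, seed: int = 0) -> dict:
    """c-index with a paired case-level bootstrap CI."""
    validate_records(records)
    s = np.asarray(scores, dtype=float)
    t = records["time_months"].to_numpy()
    e = records["event"].to_numpy(dtype=bool)
    value = c_index_value(s, t, e)
    rng = substream(seed, "cindex-boot")
    reps = []
    n = len(s)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            reps.append(c_index_value(s[idx], t[idx], e[idx]))
        except ValueError:
            continue
    lo, hi = (np.percentile(reps, [2.5, 97.5]) if reps else (np.nan, np.nan))
    return {"c_index": value, "ci": (float(lo), float(hi)), "n": n}


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow, Newton)


@dataclass
class CoxFitResult:
    summary: pd.DataFrame  # coef, hr, ci_low, ci_high, se, p per covariate
    log_likelihood: float
    coding: dict
    n: int
    n_events: int
    converged: bool
    separation_flags: list = field(default_factory=list)

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        beta = self.summary["coef"].reindex(X.columns).to_numpy()
        return X.to_numpy(dtype=float) @ beta


def _breslow_npll(beta, X, t, e):
    """Negative log Breslow partial likelihood with gradient and Hessian."""
    eta = X @ beta
    shift = eta.max()
    w = np.exp(eta - shift)
    nll, grad = 0.0, np.zeros_like(beta)
    hess = np.zeros((len(beta), len(beta)))
    for te in np.unique(t[e]):
        risk = t >= te
        tied = e & (t == te)
        d = int(tied.sum())
        wr = w[risk]
        Xr = X[risk]
        s0 = wr.sum()
        s1 = wr @ Xr
        s2 = (Xr * wr[:, None]).T @ Xr
        nll += d * (np.log(s0) + shift) - eta[tied].sum()
        grad += d * (s1 / s0) - X[tied].sum(axis=0)
        xbar = s1 / s0
        hess += d * (s2 / s0 - np.outer(xbar, xbar))
    return nll, grad, hess


def _newton_cox(X, t, e, max_iter=60, tol=1e-9):
    beta = np.zeros(X.shape[1])
    trace = []
    prev_nll = np.inf
    for it in range(max_iter):
        nll, grad, hess = _breslow_npll(beta, X, t, e)
        trace.append(nll)
        # converged when the step, the gradient, or the likelihood change is
        # negligible (a separated level gives a flat direction: the likelihood
        # plateaus while its coefficient drifts; that coefficient gets flagged)
        if np.max(np.abs(grad)) < 1e-7 or abs(prev_nll - nll) < 1e-12 * max(abs(nll), 1.0):
            return beta, nll, hess, True, trace
        prev_nll = nll
        try:
            step = np.linalg.solve(hess + 1e-10 * np.eye(len(beta)), grad)
        except np.linalg.LinAlgError as err:
            raise RuntimeError(f"singular information matrix at iteration {it}") from err
        # step-halving safeguard
        scale = 1.0
        for _ in range(30):
            cand = beta - scale * step
            if _breslow_npll(cand, X, t, e)[0] <= nll + 1e-12:
                break
            scale /= 2
        beta = beta - scale * step
        if np.max(np.abs(scale * step)) < tol:
            nll, grad, hess = _breslow_npll(beta, X, t, e)
            return beta, nll, hess, True, trace
    raise RuntimeError(f"Cox fit did not converge in {max_iter} iterations; trace={trace[-5:]}")


def build_design(
    records: pd.DataFrame,
    covariates: dict | None = None,
    score: np.ndarray | None = None,
    reference_records: pd.DataFrame | None = None,
    reference_score: np.ndarray | None = None,
) -> tuple:
    """Design matrix with the study's codings.

    ``covariates`` maps column name -> reference level for dummy coding;
    the ``age`` column (if present in the map with reference ``None``) is
    centered at the reference-split mean and scaled by 1/10.  ``score`` is
    standardized on the reference scores.  Returns ``(X, coding)``.
    """
    covariates = DEFAULT_COVARIATES if covariates is None else covariates
    ref = records if reference_records is None else reference_records
    cols = {}
    coding = {}
    if score is not None:
        ref_s = score if reference_score is None else reference_score
        z, mu, sd = standardize(np.asarray(score, float), np.asarray(ref_s, float))
        cols["score"] = z
        coding["score"] = {"standardized_on_mean": mu, "std": sd}
    if "age" in records.columns and (covariates is None or "age" not in covariates):
        mean_age = float(ref["age"].mean())
        cols["age_per_decade"] = (records["age"].to_numpy(float) - mean_age) / 10.0
        coding["age"] = {"centered_at": mean_age, "scale": 10.0}
    for col, ref_level in covariates.items():
        if col not in records.columns:
            continue
        levels = sorted(set(ref[col].astype(str)) | set(records[col].astype(str)))
        coding[col] = {"reference": ref_level, "levels": levels}
        for lev in levels:
            if lev == ref_level:
                continue
            cols[f"{col}[{lev}]"] = (records[col].astype(str) == lev).astype(float).to_numpy()
    X = pd.DataFrame(cols, index=records.index)
    # drop constant columns (e.g. absent levels)
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        X = X.drop(columns=const)
        coding["dropped_constant"] = const
    return X, coding


def fit_cox(
    records: pd.DataFrame,
    covariates: dict | None = None,
    score: np.ndarray | None = None,
    reference_records: pd.DataFrame | None = None,
    reference_score: np.ndarray | None = None,
    X: pd.DataFrame | None = None,
) -> CoxFitResult:
    """Breslow Cox regression with Wald CIs and p-values.

    Either pass a prebuilt design matrix ``X`` or records + covariate map
    (with optional risk score column, standardized on the reference split).
    """
    from scipy.stats import norm

    validate_records(records)
    if X is None:
        X, coding = build_design(records, covariates, score, reference_records, reference_score)
    else:
        coding = {"prebuilt": list(X.columns)}
    if X.shape[1] == 0:
        raise ValueError("empty design matrix")
    t = records["time_months"].to_numpy(dtype=float)
    e = records["event"].to_numpy(dtype=bool)
    n_events = int(e.sum())
    if n_events < X.shape[1]:
        raise ValueError(f"{n_events} events < {X.shape[1]} parameters")
    Xv = X.to_numpy(dtype=float)
    if any(np.ptp(Xv[:, j]) == 0 for j in range(Xv.shape[1])):
        raise ValueError("constant covariate in design matrix")

    beta, nll, hess, converged, _ = _newton_cox(Xv, t, e)
    cov = np.linalg.inv(hess + 1e-10 * np.eye(len(beta)))
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2 * norm.sf(np.abs(z))
    summary = pd.DataFrame(
        {
            "coef": beta,
            "hr": np.exp(beta),
            "ci_low": np.exp(beta - 1.96 * se),
            "ci_high": np.exp(beta + 1.96 * se),
            "se": se,
            "p": p,
        },
        index=X.columns,
    )
    flags = [c for c, b in zip(X.columns, beta) if abs(b) > 10]
    return CoxFitResult(summary, -float(nll), coding, len(records), n_events, converged, flags)


# ---------------------------------------------------------------------------
# Kaplan-Meier risk groups


@dataclass
class RiskGroups:
    assignment: pd.Series  # case_id -> low/medium/high
    thresholds: tuple  # (q25, q75) of the tune scores
    km_curves: dict  # group -> DataFrame(month, at_risk, survival, ci_low, ci_high)
    logrank_p: float  # high vs. low
    hr_table: pd.DataFrame | None  # medium/high vs. low reference


def km_risk_groups(
    tune_scores: np.ndarray,
    eval_scores: np.ndarray,
    eval_records: pd.DataFrame,
    fit_group_cox: bool = True,
) -> RiskGroups:
    """Stratify eval cases by tune-set quartile thresholds and compare survival.

    Thresholds are the 25th/75th linear-interpolation percentiles of the
    tune scores; ties land in the extreme groups (low: <= q25, high: >= q75).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    validate_records(eval_records)
    tune_scores = np.asarray(tune_scores, dtype=float)
    if tune_scores.size == 0:
        raise ValueError("empty tune threshold subset")
    q25, q75 = np.percentile(tune_scores, [25, 75])
    s = np.asarray(eval_scores, dtype=float)
    group = np.where(s <= q25, "low", np.where(s >= q75, "high", "medium"))
    assignment = pd.Series(group, index=eval_records["case_id"].to_numpy(), name="risk_group")
    if (group == "low").sum() == 0 or (group == "high").sum() == 0:
        raise ValueError("empty low or high risk group on the evaluation split")

    t = eval_records["time_months"].to_numpy()
    e = eval_records["event"].to_numpy(dtype=bool)
    curves = {}
    for g in ("low", "medium", "high"):
        m = group == g
        if m.sum() == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(t[m], e[m])
        grid = np.arange(0, int(t.max()) + 1)
        surv = kmf.survival_function_at_times(grid).to_numpy()
        ci = kmf.confidence_interval_survival_function_
        ci_lo = np.interp(grid, ci.index.to_numpy(), ci.iloc[:, 0].to_numpy())
        ci_hi = np.interp(grid, ci.index.to_numpy(), ci.iloc[:, 1].to_numpy())
        at_risk = np.array([(t[m] >= month).sum() for month in grid])
        curves[g] = pd.DataFrame(
            {"month": grid, "at_risk": at_risk, "survival": surv,
             "ci_low": ci_lo, "ci_high": ci_hi}
        )

    hl = (group == "high") | (group == "low")
    lr = logrank_test(
        t[group == "high"], t[group == "low"], e[group == "high"], e[group == "low"]
    )
    hr_table = None
    if fit_group_cox:
        df = eval_records.loc[:, ["case_id", "time_months", "event", "censor_reason"]].copy()
        df["risk_group"] = group
        try:
            fit = fit_cox(df, covariates={"risk_group": "low"})
            hr_table = fit.summary
        except (ValueError, RuntimeError):
            hr_table = None
    return RiskGroups(assignment, (float(q25), float(q75)), curves, float(lr.p_value), hr_table)


# ---------------------------------------------------------------------------
# added predictive value


def added_value_report(
    fit_records: pd.DataFrame,
    fit_scores: np.ndarray,
    eval_records: pd.DataFrame,
    eval_scores: np.ndarray,
    covariates: dict | None = None,
    horizon: int = 60,
    n_boot: int = 500,
    seed: int = 0,
) -> dict:
    """Compare a clinicopathologic baseline Cox model against the same model
    plus the risk score: horizon-AUC and c-index deltas with paired
    bootstrap CIs.  Both models are fit on the fitting split and applied to
    the evaluation split."""
    Xf_base, _ = build_design(fit_records, covariates)
    Xf_comb, _ = build_design(fit_records, covariates, score=fit_scores)
    base_fit = fit_cox(fit_records, X=Xf_base)
    comb_fit = fit_cox(fit_records, X=Xf_comb)

    Xe_base, _ = build_design(eval_records, covariates, reference_records=fit_records)
    Xe_comb, _ = build_design(
        eval_records, covariates, score=eval_scores,
        reference_records=fit_records, reference_score=fit_scores,
    )
    Xe_base = Xe_base.reindex(columns=Xf_base.columns, fill_value=0.0)
    Xe_comb = Xe_comb.reindex(columns=Xf_comb.columns, fill_value=0.0)
    lp_base = base_fit.linear_predictor(Xe_base)
    lp_comb = comb_fit.linear_predictor(Xe_comb)

    auc_b = five_year_auc(lp_base, eval_records, horizon, n_boot=0)["auc"]
    auc_c = five_year_auc(lp_comb, eval_records, horizon, n_boot=0)["auc"]
    t = eval_records["time_months"].to_numpy()
    e = eval_records["event"].to_numpy(dtype=bool)
    ci_b = c_index_value(lp_base, t, e)
    ci_c = c_index_value(lp_comb, t, e)

    rng = substream(seed, "added-value-boot")
    pos, neg, _ = horizon_classes(eval_records, horizon)
    keep = pos | neg
    d_auc_reps, d_ci_reps = [], []
    n = len(eval_records)
    from sklearn.metrics import roc_auc_score

    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        y = pos[idx][keep[idx]]
        if len(y) and y.min() != y.max():
            d_auc_reps.append(
                roc_auc_score(y, lp_comb[idx][keep[idx]])
                - roc_auc_score(y, lp_base[idx][keep[idx]])
            )
        try:
            d_ci_reps.append(
                c_index_value(lp_comb[idx], t[idx], e[idx])
                - c_index_value(lp_base[idx], t[idx], e[idx])
            )
        except ValueError:
            pass
    out = {
        "auc_baseline": auc_b,
        "auc_combined": auc_c,
        "delta_auc": auc_c - auc_b,
        "c_index_baseline": ci_b,
        "c_index_combined": ci_c,
        "delta_c_index": ci_c - ci_b,
    }
    if d_auc_reps:
        out["delta_auc_ci"] = tuple(np.percentile(d_auc_reps, [2.5, 97.5]))
    if d_ci_reps:
        out["delta_c_index_ci"] = tuple(np.percentile(d_ci_reps, [2.5, 97.5]))
    return out
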