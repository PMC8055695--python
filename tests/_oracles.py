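"""Independent brute-force oracles used to validate the package's
implementations.  Everything here is written as plain loops / enumeration /
generic optimization, deliberately sharing no code with the package paths
it checks."""

from __future__ import annotations

import math

import numpy as np


def cox_loss_breslow(scores, times, events) -> float:
    """Negative log partial likelihood by direct enumeration: every observed
    event contributes -(score - log sum of exp(score) over everyone still at
    risk at its event time); tied events share the denominator."""
    total = 0.0
    for i in range(len(scores)):
        if not events[i]:
            continue
        denom = 0.0
        for j in range(len(scores)):
            if times[j] >= times[i]:
                denom += math.exp(scores[j])
        total -= scores[i] - math.log(denom)
    return total


def c_index_pairs(scores, times, events) -> float:
    """Exhaustive pair enumeration: a pair counts iff the strictly earlier
    time is an observed event; concordant = higher score on the earlier
    case; tied scores count 1/2."""
    num = 0.0
    den = 0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if i == j or not events[i] or not (times[i] < times[j]):
                continue
            den += 1
            if scores[i] > scores[j]:
                num += 1.0
            elif scores[i] == scores[j]:
                num += 0.5
    if den == 0:
        raise ValueError("no admissible pairs")
    return num / den


def horizon_auc_pairs(scores, times, events, reasons, horizon=60) -> float:
    """Rank AUC over all (positive, negative) pairs after applying the
    exclusion rule by literal case-by-case classification."""
    pos, neg = [], []
    for s, t, e, r in zip(scores, times, events, reasons):
        if e and t <= horizon:
            pos.append(s)
        elif (not e) and t < horizon:
            continue  # censored before horizon: uninformative, excluded
        else:
            neg.append(s)
    if not pos or not neg:
        raise ValueError("degenerate classes")
    num = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                num += 1.0
            elif p == q:
                num += 0.5
    return num / (len(pos) * len(neg))


def flood_fill_components(mask, connectivity=8):
    """Connected components by breadth-first flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    if connectivity == 4:
        offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    comps = []
    h, w = mask.shape
    for y in range(h):
        for x in range(w):
            if mask[y, x] and not seen[y, x]:
                comp = []
                stack = [(y, x)]
                seen[y, x] = True
                while stack:
                    cy, cx = stack.pop()
                    comp.append((cy, cx))
                    for dy, dx in offs:
                        ny, nx = cy + dy, cx + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
                comps.append(comp)
    return comps


def denoise_oracle(mask, min_component=8, connectivity=8):
    out = np.zeros_like(np.asarray(mask, dtype=bool))
    for comp in flood_fill_components(mask, connectivity):
        if len(comp) >= min_component:
            for y, x in comp:
                out[y, x] = True
    return out


def dilate_oracle(mask, r):
    """Dilation by explicit offset enumeration (dy^2 + dx^2 <= r^2)."""
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros_like(mask)
    offs = [
        (dy, dx)
        for dy in range(-r, r + 1)
        for dx in range(-r, r + 1)
        if dy * dy + dx * dx <= r * r
    ]
    h, w = mask.shape
    for y in range(h):
        for x in range(w):
            if mask[y, x]:
                for dy, dx in offs:
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w:
                        out[ny, nx] = True
    return out


def cox_fit_oracle(X, times, events):
    """Maximize the Breslow partial likelihood with a generic optimizer."""
    from scipy.optimize import minimize

    X = np.asarray(X, dtype=float)

    def npll(beta):
        return cox_loss_breslow(X @ beta, times, events)

    res = minimize(npll, np.zeros(X.shape[1]), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    res2 = minimize(npll, res.x, method="Powell",
                    options={"xtol": 1e-12, "ftol": 1e-14})
    return res2.x


def best_subset_r2(X, y, size):
    """Exhaustive best subset by plain R^2 via lstsq (for stepwise checks)."""
    from itertools import combinations

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    best = (-np.inf, None)
    for combo in combinations(range(X.shape[1]), size):
        Z = np.column_stack([np.ones(len(y)), X[:, combo]])
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ beta
        r2 = 1 - resid @ resid / ((y - y.mean()) ** 2).sum()
        if r2 > best[0]:
            best = (r2, combo)
    return best
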