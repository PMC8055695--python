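"""Shared domain types and small utilities used across the pipeline.

The canonical in-memory container for case-level survival data is a pandas
DataFrame (a "records frame") with at least the columns in
:data:`RECORD_COLUMNS`; clinicopathologic covariates ride along as extra
columns.  Time is in whole months (>= 1), ``event`` is a boolean
disease-specific event indicator, and ``censor_reason`` distinguishes
disease events from non-disease death and administrative censoring.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: reasons recorded in the ``censor_reason`` column
CENSOR_DISEASE = "disease_event"
CENSOR_NONDISEASE = "non_disease_death"
CENSOR_ADMIN = "admin"

RECORD_COLUMNS = ("case_id", "time_months", "event", "censor_reason")

#: splits used throughout (development = train + tune; val2 is temporal)
SPLITS = ("train", "tune", "val1", "val2")


@dataclass(frozen=True)
class SurvivalRecord:
    """One case's outcome: time T_i (months), event indicator O_i, censor reason."""

    case_id: str
    time_months: int
    event: bool
    censor_reason: str

    def __post_init__(self) -> None:
        if self.time_months < 1:
            raise ValueError("survival time must be >= 1 month")
        if self.event and self.censor_reason != CENSOR_DISEASE:
            raise ValueError("observed events must carry the disease censor reason")


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Validate a records frame; returns it unchanged on success."""
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records frame missing columns: {missing}")
    if (records["time_months"] < 1).any():
        raise ValueError("all survival times must be >= 1 month")
    bad = records["event"].astype(bool) & (records["censor_reason"] != CENSOR_DISEASE)
    if bad.any():
        raise ValueError("event=True rows must have censor_reason=disease_event")
    return records


def substream(seed: int, *key) -> np.random.Generator:
    """Derive a named, independent random generator from a global seed.

    All randomness in the package flows from a single integer seed through
    named substreams so stages can be re-run independently yet reproducibly.
    """
    h = zlib.crc32("/".join(str(k) for k in key).encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, h]))


def allocate_counts(n: int, weights: np.ndarray) -> np.ndarray:
    """Split integer ``n`` proportionally to ``weights`` (largest remainder)."""
    weights = np.asarray(weights, dtype=float)
    if n < 0 or (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("need n >= 0 and nonnegative weights with positive sum")
    quota = n * weights / weights.sum()
    counts = np.floor(quota).astype(int)
    rem = n - counts.sum()
    if rem > 0:
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:rem]] += 1
    return counts


def trailing_rolling_mean(series: np.ndarray, window: int) -> np.ndarray:
    """Causal rolling mean: position i averages the last min(window, i+1) values."""
    x = np.asarray(series, dtype=float)
    out = np.empty_like(x)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    for i in range(len(x)):
        lo = max(0, i - window + 1)
        out[i] = (csum[i + 1] - csum[lo]) / (i + 1 - lo)
    return out


def standardize(values: np.ndarray, reference: np.ndarray | None = None):
    """Zero-mean unit-variance rescaling using reference-split statistics.

    Returns ``(standardized, mean, std)``; raises on a constant reference.
    """
    values = np.asarray(values, dtype=float)
    ref = values if reference is None else np.asarray(reference, dtype=float)
    mu = float(ref.mean())
    sd = float(ref.std())
    if sd == 0:
        raise ValueError("cannot standardize against a constant reference")
    return (values - mu) / sd, mu, sd
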