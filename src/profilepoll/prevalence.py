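"""Stunting severity classification and weighted prevalence tables.

Stunting follows the WHO height-for-age convention: a child is stunted when
HAZ < -2 SD of the reference median, severely stunted when HAZ < -3 SD, and
moderately stunted for -3 <= HAZ < -2. Boundary values go to the less severe
class (strict ``<``). Prevalence is the survey-weighted proportion
sum(w * 1[outcome]) / sum(w), reported with the unweighted n per stratum so
small strata remain auditable. District prevalences can be banded into the
four map classes <=30%, 30-40%, 40-50% and >=50%.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .recode import CodedDataset

logger = logging.getLogger("profilepoll")

OUTCOMES = ("total", "severe", "moderate")

#: (label, lower, upper, lower_inclusive, upper_inclusive) on the proportion scale
BANDS = (
    ("<=30%", 0.0, 0.30, True, True),
    ("30-40%", 0.30, 0.40, False, False),
    ("40-50%", 0.40, 0.50, True, False),
    (">=50%", 0.50, 1.0, True, True),
)


def classify_stunting(haz: float) -> str:
    """Map one HAZ value to {not_stunted, moderate, severe}."""
    if haz is None or not math.isfinite(haz):
        raise ValueError("HAZ must be finite; missing HAZ has no stunting class")
    if haz < -3:
        return "severe"
    if haz < -2:
        return "moderate"
    return "not_stunted"


def stunting_indicator(haz: np.ndarray | pd.Series, outcome: str = "total") -> np.ndarray:
    """Vectorised 0/1 indicator for the requested severity outcome."""
    z = np.asarray(haz, dtype=float)
    if outcome == "total":
        return (z < -2).astype(float)
    if outcome == "severe":
        return (z < -3).astype(float)
    if outcome == "moderate":
        return ((z < -2) & (z >= -3)).astype(float)
    raise ValueError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")


def weighted_prevalence(
    ds: CodedDataset, outcome: str = "total", by: str | None = None
) -> pd.DataFrame:
    """Weighted stunting prevalence, optionally stratified by one variable.

    Returns columns ``stratum, outcome, n_unweighted, weighted_prevalence``;
    an unstratified call returns the single row ``stratum="all"``. Records
    with missing HAZ (or a missing stratifier value) are dropped; empty
    strata are omitted with a warning.
    """
    df = ds.df[ds.df["haz"].notna()]
    if by is not None and by not in df.columns:
        raise KeyError(f"stratifier {by!r} not in dataset")
    if by is not None:
        n_miss = int(df[by].isna().sum())
        if n_miss:
            logger.warning("weighted_prevalence: dropped %d record(s) missing %s", n_miss, by)
        df = df[df[by].notna()]
    ind = stunting_indicator(df["haz"].to_numpy(), outcome)
    w = df["weight"].to_numpy(dtype=float)
    rows = []
    if by is None:
        groups = [("all", np.ones(len(df), dtype=bool))]
    else:
        labels = df[by].to_numpy()
        groups = [(lab, labels == lab) for lab in sorted(pd.unique(labels))]
    for label, mask in groups:
        if not mask.any():
            logger.warning("weighted_prevalence: empty stratum %r omitted", label)
            continue
        rows.append(
            {
                "stratum": label,
                "outcome": outcome,
                "n_unweighted": int(mask.sum()),
                "weighted_prevalence": float(
                    np.sum(w[mask] * ind[mask]) / np.sum(w[mask])
                ),
            }
        )
    return pd.DataFrame(rows, columns=["stratum", "outcome", "n_unweighted", "weighted_prevalence"])


def assign_band(prevalence: float) -> str:
    """Band one prevalence value into the four map classes."""
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError(f"prevalence {prevalence} outside [0, 1]")
    for label, lo, hi, lo_incl, hi_incl in BANDS:
        above = prevalence > lo or (lo_incl and prevalence == lo)
        below = prevalence < hi or (hi_incl and prevalence == hi)
        if above and below:
            return label
    raise AssertionError("bands must partition [0, 1]")  # pragma: no cover


def district_banding(prevalence_table: pd.DataFrame) -> pd.DataFrame:
    """Attach the map band to a district-stratified prevalence table."""
    out = prevalence_table.rename(columns={"stratum": "district"}).copy()
    out["band"] = [assign_band(p) for p in out["weighted_prevalence"]]
    return out[["district", "n_unweighted", "weighted_prevalence", "band"]]
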