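"""Univariate screening of candidate covariates against stunting.

For each candidate variable this computes the weighted stunting prevalence
per category together with one Pearson chi-square test of independence on
the weighted outcome-by-category table. The weighted table is rescaled so
its grand total equals the unweighted sample size before testing — weights
shape the cell proportions but do not inflate the evidence. No design-based
(Rao-Scott) correction is applied: screening here is a gate into the
profile search, not an inferential endpoint.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .prevalence import stunting_indicator
from .recode import CodedDataset

_OUTCOME_MAP = {"total": "total", "severe": "severe", "moderate": "moderate"}


def weighted_chi2(
    outcome: np.ndarray, category_codes: np.ndarray, weights: np.ndarray
) -> tuple[float, float]:
    """Pearson chi-square on the weighted 2xK table rescaled to unweighted n.

    Returns ``(statistic, p_value)``; ``(nan, nan)`` when the table is
    degenerate (a single observed category or a constant outcome).
    """
    n = len(outcome)
    k = int(category_codes.max()) + 1 if n else 0
    table = np.zeros((2, k))
    for g in (0, 1):
        mask = outcome == g
        table[g] = np.bincount(category_codes[mask], weights=weights[mask], minlength=k)
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
        return float("nan"), float("nan")
    table = table * (n / table.sum())
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def screen_variable(
    ds: CodedDataset, variable: str, outcome: str = "total"
) -> pd.DataFrame:
    """Per-category weighted prevalence plus one chi-square test per variable.

    Complete cases on {variable, HAZ}. Returns one row per observed
    category, all carrying the same (statistic, p_value); a single-category
    variable yields rows with the test left missing.
    """
    if variable not in ds.variable_names:
        raise KeyError(f"variable {variable!r} not in codebook")
    df = ds.df[ds.df["haz"].notna() & ds.df[variable].notna()]
    if len(df) == 0:
        raise ValueError(f"no complete cases for {variable!r}")
    ind = stunting_indicator(df["haz"].to_numpy(), _OUTCOME_MAP[outcome]).astype(int)
    w = df["weight"].to_numpy(dtype=float)
    spec = ds.variable(variable)
    observed = [c for c in spec.categories if (df[variable] == c).any()]
    codes = pd.Categorical(df[variable], categories=observed).codes.astype(np.int64)
    stat, p = weighted_chi2(ind, codes, w)
    rows = []
    for j, cat in enumerate(observed):
        mask = codes == j
        rows.append(
            {
                "variable": variable,
                "category": cat,
                "n": int(mask.sum()),
                "prevalence": float(np.sum(w[mask] * ind[mask]) / np.sum(w[mask])),
                "test_statistic": stat,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def screen_all(
    ds: CodedDataset, variables: list[str] | None = None, outcome: str = "total"
) -> pd.DataFrame:
    """Screening table for many variables, in codebook order (S1-style layout)."""
    if variables is None:
        variables = ds.variable_names
    return pd.concat(
        [screen_variable(ds, v, outcome) for v in variables], ignore_index=True
    )


def build_candidate_set(
    screening: pd.DataFrame,
    codebook_order: list[str],
    p_threshold: float = 0.05,
    force_include: list[str] | None = None,
    exclude: list[str] | None = None,
) -> list[str]:
    """Select the polled candidate variables from screening results.

    A variable enters when its p-value passes ``p_threshold`` or it is
    force-included (screening informs but does not strictly gate inclusion);
    explicit exclusions — typically the stratifier, since polling runs
    within strata — always win. Output order follows the codebook.
    """
    force_include = set(force_include or ())
    exclude = set(exclude or ())
    p_by_var = (
        screening.drop_duplicates("variable").set_index("variable")["p_value"].to_dict()
    )
    chosen = []
    for name in codebook_order:
        if name in exclude or name not in p_by_var:
            continue
        p = p_by_var[name]
        if name in force_include or (np.isfinite(p) and p < p_threshold):
            chosen.append(name)
    return chosen
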