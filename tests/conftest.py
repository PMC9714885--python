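from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from profilepoll.recode import CodedDataset, VariableSpec


def make_dataset(rows: list[dict], codebook: list[VariableSpec] | None = None,
                 label: str = "fixture") -> CodedDataset:
    """Build a CodedDataset from plain row dicts, inferring the codebook."""
    df = pd.DataFrame(rows)
    for col in ("division", "district", "cluster_id"):
        if col not in df.columns:
            df[col] = "0"
    if codebook is None:
        covars = [c for c in df.columns
                  if c not in ("haz", "weight", "division", "district", "cluster_id")]
        codebook = [
            VariableSpec(c, tuple(sorted(df[c].dropna().unique()))) for c in covars
        ]
    return CodedDataset(df=df, codebook=codebook, survey_label=label)


def random_dataset(rng: np.random.Generator, n_max: int = 1000,
                   max_vars: int = 6, max_cats: int = 3) -> CodedDataset:
    """Small randomised dataset for oracle-equivalence checks."""
    n = int(rng.integers(50, n_max + 1))
    n_vars = int(rng.integers(2, max_vars + 1))
    rows = []
    var_cats = {
        f"v{j}": [f"c{l}" for l in range(int(rng.integers(2, max_cats + 1)))]
        for j in range(n_vars)
    }
    for _ in range(n):
        row = {
            "haz": float(rng.normal(-1.5, 1.5)),
            "weight": float(rng.lognormal(0.0, 0.5)),
        }
        for v, cats in var_cats.items():
            row[v] = cats[int(rng.integers(0, len(cats)))]
        rows.append(row)
    return make_dataset(rows)


@pytest.fixture
def four_children() -> CodedDataset:
    """Four equal-weight children spanning all three stunting classes."""
    return make_dataset(
        [
            {"haz": -2.5, "weight": 1.0, "residence": "rural"},
            {"haz": -1.0, "weight": 1.0, "residence": "rural"},
            {"haz": -3.5, "weight": 1.0, "residence": "urban"},
            {"haz": 0.0, "weight": 1.0, "residence": "urban"},
        ]
    )
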