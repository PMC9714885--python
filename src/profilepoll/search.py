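"""Exhaustive search over k-variable covariate subsets per stratum.

Every C(n, k) unordered subset of the candidate variables is polled on each
stratum's own complete cases (national = no stratum filter; otherwise the
records of one division), and the per-stratum winner is selected by a
deterministic ranking — by default highest coverage, ties broken by edge,
then by lexicographic subset order. With the standard 11 candidates and
k = 5 this is 462 polling analyses per stratum.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .polling import (
    InsufficientSupportError,
    JointMass,
    PollingResult,
    joint_distribution,
    poll,
)
from .recode import CodedDataset

RANKINGS = ("coverage-then-edge", "edge-then-coverage", "product")

NATIONAL = "national"


def enumerate_subsets(
    candidates: Sequence[str], k: int
) -> list[tuple[str, ...]]:
    """All C(n, k) unordered subsets, lexicographic in candidate order."""
    candidates = tuple(candidates)
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds {len(candidates)} candidates")
    if k < 1:
        raise ValueError("k must be >= 1")
    return list(combinations(candidates, k))


@dataclass
class SearchConfig:
    """Parameters of one exhaustive profile search."""

    candidates: list[str]
    k: int = 5
    strata: list[str] | None = None  # None -> national + observed divisions
    outcome: str = "stunted_total"
    convention: str = "coverage-rank"
    min_cell: int = 25
    ranking: str = "coverage-then-edge"

    def __post_init__(self) -> None:
        if not 1 <= self.k <= len(self.candidates):
            raise ValueError("need 1 <= k <= len(candidates)")
        if self.ranking not in RANKINGS:
            raise ValueError(f"unknown ranking {self.ranking!r}")

    def to_dict(self) -> dict:
        return {
            "candidates": list(self.candidates),
            "k": self.k,
            "strata": list(self.strata) if self.strata is not None else None,
            "outcome": self.outcome,
            "convention": self.convention,
            "min_cell": self.min_cell,
            "ranking": self.ranking,
        }


@dataclass
class StratumSearch:
    """Ranked polling results for one stratum."""

    stratum: str
    ranked: list[PollingResult]
    n_insufficient: int

    @property
    def chosen(self) -> PollingResult | None:
        return self.ranked[0] if self.ranked else None


@dataclass
class SearchResult:
    """Full search output: per-stratum ranked lists and the chosen entries."""

    config: SearchConfig
    per_stratum: dict[str, StratumSearch]
    n_analyses: int

    @property
    def chosen(self) -> dict[str, PollingResult | None]:
        return {s: ss.chosen for s, ss in self.per_stratum.items()}

    def to_manifest(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "n_analyses": self.n_analyses,
            "strata": {
                s: {
                    "n_ranked": len(ss.ranked),
                    "n_insufficient": ss.n_insufficient,
                    "chosen": ss.chosen.to_dict() if ss.chosen else None,
                }
                for s, ss in self.per_stratum.items()
            },
        }

    def winners_table(self) -> pd.DataFrame:
        """Per-stratum winner in the published-table layout."""
        rows = []
        for stratum, ss in self.per_stratum.items():
            if ss.chosen is None:
                rows.append({"stratum": stratum, "profile": "(insufficient support)",
                             "coverage": float("nan"), "edge": float("nan"),
                             "n_effective": 0})
                continue
            r = ss.chosen
            rows.append(
                {
                    "stratum": stratum,
                    "profile": str(r.winner),
                    "coverage": round(r.coverage, 2),
                    "edge": round(r.edge, 2),
                    "n_effective": r.n_effective,
                }
            )
        return pd.DataFrame(rows)

    def ranked_table(self) -> pd.DataFrame:
        rows = []
        for stratum, ss in self.per_stratum.items():
            for rank, r in enumerate(ss.ranked, start=1):
                rows.append(
                    {
                        "stratum": stratum,
                        "rank": rank,
                        "subset": "+".join(r.subset),
                        "winner": str(r.winner),
                        "coverage": r.coverage,
                        "edge": r.edge,
                        "n_effective": r.n_effective,
                    }
                )
        return pd.DataFrame(rows)


def _rank_key(ranking: str):
    if ranking == "coverage-then-edge":
        return lambda r: (-r.coverage, -r.edge, r.subset)
    if ranking == "edge-then-coverage":
        return lambda r: (-r.edge, -r.coverage, r.subset)
    # product: coverage * log(edge); degenerate edge=1 scores zero
    return lambda r: (-(r.coverage * math.log(r.edge)) if r.edge > 1 else 0.0, r.subset)


def _precode(ds: CodedDataset, candidates: Sequence[str]):
    """Factorise candidate columns once; codes < 0 mark missing."""
    coded = {}
    for var in candidates:
        if var not in ds.df.columns:
            raise KeyError(f"candidate {var!r} not in dataset")
        codes, labels = pd.factorize(ds.df[var], use_na_sentinel=True)
        coded[var] = (codes, np.asarray(labels, dtype=object))
    return coded


def run_search(ds: CodedDataset, cfg: SearchConfig) -> SearchResult:
    """Poll every k-subset in every stratum and rank by ``cfg.ranking``.

    Complete cases are re-selected per subset inside
    :func:`joint_distribution`, so each analysis keeps its own maximal
    sample. Subsets with insufficient support are excluded and counted.
    """
    subsets = enumerate_subsets(cfg.candidates, cfg.k)
    if cfg.strata is None:
        divisions = sorted(ds.df["division"].dropna().unique())
        strata = [NATIONAL] + [str(d) for d in divisions]
    else:
        strata = list(cfg.strata)

    per_stratum: dict[str, StratumSearch] = {}
    for stratum in strata:
        if stratum == NATIONAL:
            sub_ds = ds
        else:
            sub = ds.df[ds.df["division"] == stratum]
            sub_ds = CodedDataset(
                df=sub.reset_index(drop=True),
                codebook=ds.codebook,
                survey_label=ds.survey_label,
            )
        if len(sub_ds.df) == 0:
            per_stratum[stratum] = StratumSearch(stratum, [], len(subsets))
            continue
        precoded = _precode(sub_ds, cfg.candidates)
        results: list[PollingResult] = []
        n_insufficient = 0
        for subset in subsets:
            try:
                jm = joint_distribution(
                    sub_ds, subset, cfg.outcome, precoded=precoded
                )
                r = poll(jm, g=1, convention=cfg.convention, min_cell=cfg.min_cell)
            except (InsufficientSupportError, ValueError):
                n_insufficient += 1
                continue
            r.outcome = cfg.outcome
            r.stratum = stratum
            results.append(r)
        results.sort(key=_rank_key(cfg.ranking))
        per_stratum[stratum] = StratumSearch(stratum, results, n_insufficient)
    return SearchResult(config=cfg, per_stratum=per_stratum, n_analyses=len(subsets))


# ---------------------------------------------------------------------------
# run IO and survey comparison


def write_run(result: SearchResult, outdir: str | Path) -> None:
    """Write winners table, full ranked list and a deterministic manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.winners_table().to_csv(outdir / "winners.csv", index=False)
    result.ranked_table().to_csv(outdir / "ranked.csv", index=False)
    manifest = json.dumps(result.to_manifest(), sort_keys=True, indent=2)
    (outdir / "manifest.json").write_text(manifest + "\n")


def load_manifest(rundir: str | Path) -> dict:
    return json.loads((Path(rundir) / "manifest.json").read_text())


def compare_manifests(manifest_a: dict, manifest_b: dict,
                      label_a: str = "a", label_b: str = "b") -> pd.DataFrame:
    """Change report between two search runs' winning profiles per stratum.

    Lists variables entering/leaving the winning profile, coverage and edge
    deltas, and flags increased profile diversity when coverage fell. Strata
    present in only one run are reported as not comparable.
    """
    strata = sorted(set(manifest_a["strata"]) | set(manifest_b["strata"]))
    rows = []
    for stratum in strata:
        entry_a = manifest_a["strata"].get(stratum, {}).get("chosen")
        entry_b = manifest_b["strata"].get(stratum, {}).get("chosen")
        if entry_a is None or entry_b is None:
            rows.append({"stratum": stratum, "comparable": False,
                         "entered": "", "left": "", "coverage_delta": float("nan"),
                         "edge_delta": float("nan"), "diversity_increased": False})
            continue
        vars_a, vars_b = set(entry_a["winner"]), set(entry_b["winner"])
        d_cov = entry_b["coverage"] - entry_a["coverage"]
        rows.append(
            {
                "stratum": stratum,
                "comparable": True,
                "entered": "+".join(sorted(vars_b - vars_a)),
                "left": "+".join(sorted(vars_a - vars_b)),
                "coverage_delta": d_cov,
                "edge_delta": entry_b["edge"] - entry_a["edge"],
                "diversity_increased": bool(d_cov < 0),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["labels"] = (label_a, label_b)
    return out


def compare_surveys(results: dict[str, SearchResult]) -> pd.DataFrame:
    """Compare winning profiles across >= 2 survey-year SearchResults."""
    if len(results) < 2:
        raise ValueError("need at least two survey results to compare")
    (la, ra), (lb, rb) = list(results.items())[:2]
    return compare_manifests(ra.to_manifest(), rb.to_manifest(), la, lb)
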