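"""Maximum-likelihood profile "polling" over weighted categorical data.

The estimator works on the weighted empirical joint distribution of a binary
outcome g (stunted / not stunted) and a covariate *profile* c — one category
value per variable in a chosen subset. With survey weights w_s, the mass of
cell (g, c) is m_gc = sum of w_s over records whose profile equals c and
outcome equals g. From the cell masses:

* conditional frequency  P(g|c) = m_gc / sum_g' m_g'c
* coverage of profile c  m_gc / m_g      (m_g = total mass of outcome group g)
* edge of the winner     ratio of the winner's score to the runner-up's

Two ranking conventions are supported. ``coverage-rank`` (default) ranks
profiles by their mass within the outcome group — the winner is the profile
covering the largest weighted share of stunted children, and the edge is the
ratio of the top two coverages. ``conditional-rank`` ranks by P(g|c) — the
winner is the profile with the highest conditional probability of the
outcome, and the edge is the ratio of the top two conditional probabilities.
Both report coverage of the winner the same way. Ties are broken
lexicographically on the profile's category values and flagged.

A minimum unweighted support per candidate cell (``min_cell``) guards
against single-record profiles trivially winning under conditional-rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .recode import CodedDataset

#: outcome codings: name -> HAZ threshold defining g = 1
OUTCOME_CODINGS = {"stunted_total": -2.0, "stunted_severe": -3.0}

CONVENTIONS = ("coverage-rank", "conditional-rank")

_TIE_RTOL = 1e-12


class InsufficientSupportError(ValueError):
    """Fewer than two profiles meet the support threshold for the outcome."""


class UndefinedProfileError(KeyError):
    """The requested profile was never observed in the joint distribution."""


@dataclass(frozen=True)
class Profile:
    """An assignment of one category value to each variable in a subset."""

    variables: tuple[str, ...]
    values: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.variables) != len(self.values):
            raise ValueError("variables and values must have equal length")

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.variables, self.values))

    def __str__(self) -> str:
        return "; ".join(f"{v}={c}" for v, c in zip(self.variables, self.values))


@dataclass
class JointMass:
    """Weighted joint distribution of (outcome, profile) over one subset.

    ``cells`` maps (g, profile-values-tuple) to total weight; ``counts``
    carries the unweighted record count per cell. Zero-mass cells are absent.
    """

    subset: tuple[str, ...]
    cells: dict[tuple[int, tuple[str, ...]], float]
    counts: dict[tuple[int, tuple[str, ...]], int]
    total_mass: float
    n_records: int

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def profiles(self) -> list[tuple[str, ...]]:
        return sorted({c for _, c in self.cells})

    def outcome_mass(self, g: int) -> float:
        return sum(m for (gg, _), m in self.cells.items() if gg == g)


def joint_distribution(
    ds: CodedDataset,
    subset: Sequence[str],
    outcome: str = "stunted_total",
    *,
    precoded: Mapping[str, tuple[np.ndarray, np.ndarray]] | None = None,
) -> JointMass:
    """Accumulate cell masses m_gc = sum of weights over matching records.

    Complete cases on ``subset`` plus HAZ are selected internally (the
    per-analysis listwise policy). ``precoded`` optionally supplies
    pre-factorised integer codes per variable (codes, labels) aligned to
    ``ds.df`` rows, which the exhaustive search uses to avoid re-factorising
    the same columns hundreds of times; codes < 0 mark missing values.
    """
    subset = tuple(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    if outcome not in OUTCOME_CODINGS:
        raise ValueError(f"unknown outcome {outcome!r}")
    threshold = OUTCOME_CODINGS[outcome]

    df = ds.df
    haz = df["haz"].to_numpy(dtype=float)
    valid = np.isfinite(haz)

    codes_list: list[np.ndarray] = []
    labels_list: list[np.ndarray] = []
    for var in subset:
        if precoded is not None and var in precoded:
            codes, labels = precoded[var]
        else:
            if var not in df.columns:
                raise KeyError(f"variable {var!r} not in dataset")
            codes, labels = pd.factorize(df[var], use_na_sentinel=True)
            labels = np.asarray(labels, dtype=object)
        codes_list.append(codes)
        labels_list.append(labels)
        valid &= codes >= 0

    if not valid.any():
        raise ValueError("empty dataset after complete-case selection")

    g = (haz[valid] < threshold).astype(np.int64)
    w = df["weight"].to_numpy(dtype=float)[valid]

    # mixed-radix key over the subset's category codes, interleaved with g
    key = np.zeros(int(valid.sum()), dtype=np.int64)
    radices = [len(lab) for lab in labels_list]
    for codes, radix in zip(codes_list, radices):
        key = key * radix + codes[valid]
    key = key * 2 + g

    uniq, inv = np.unique(key, return_inverse=True)
    masses = np.bincount(inv, weights=w, minlength=len(uniq))
    counts = np.bincount(inv, minlength=len(uniq))

    cells: dict[tuple[int, tuple[str, ...]], float] = {}
    cell_counts: dict[tuple[int, tuple[str, ...]], int] = {}
    for k, mass, count in zip(uniq.tolist(), masses.tolist(), counts.tolist()):
        gg = k % 2
        k //= 2
        values = []
        for labels, radix in zip(reversed(labels_list), reversed(radices)):
            values.append(labels[k % radix])
            k //= radix
        c = tuple(reversed(values))
        cells[(gg, c)] = mass
        cell_counts[(gg, c)] = int(count)
    return JointMass(
        subset=subset,
        cells=cells,
        counts=cell_counts,
        total_mass=float(np.sum(w)),
        n_records=int(valid.sum()),
    )


def conditional_frequency(jm: JointMass, g: int, c: tuple[str, ...] | Profile) -> float:
    """P(g | c) = m_gc / sum_g' m_g'c for an observed profile c."""
    values = c.values if isinstance(c, Profile) else tuple(c)
    denom = sum(jm.cells.get((gg, values), 0.0) for gg in (0, 1))
    if denom == 0.0:
        raise UndefinedProfileError(f"profile {values!r} not observed")
    return jm.cells.get((g, values), 0.0) / denom


@dataclass
class PollingResult:
    """Winner, runner-up, coverage and edge for one (subset, outcome) poll."""

    subset: tuple[str, ...]
    outcome: str
    convention: str
    winner: Profile
    runner_up: Profile
    coverage: float
    edge: float
    tied: bool
    n_effective: int
    n_profiles: int
    stratum: str = "national"
    winner_score: float = field(default=float("nan"), repr=False)
    runner_up_score: float = field(default=float("nan"), repr=False)

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "subset": list(self.subset),
            "outcome": self.outcome,
            "convention": self.convention,
            "winner": self.winner.as_dict(),
            "runner_up": self.runner_up.as_dict(),
            "coverage": self.coverage,
            "edge": self.edge,
            "tied": self.tied,
            "n_effective": self.n_effective,
            "n_profiles": self.n_profiles,
        }


def poll(
    jm: JointMass,
    g: int = 1,
    convention: str = "coverage-rank",
    min_cell: int = 25,
) -> PollingResult:
    """Rank profiles for outcome ``g`` and report winner, coverage and edge.

    Raises :class:`InsufficientSupportError` when fewer than two profiles
    have cell mass for ``g`` with unweighted support >= ``min_cell``.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; expected {CONVENTIONS}")
    group_cells = {c: m for (gg, c), m in jm.cells.items() if gg == g}
    m_g = sum(group_cells.values())
    if m_g <= 0:
        raise InsufficientSupportError(f"no mass for outcome {g}")

    eligible = {
        c: m for c, m in group_cells.items() if jm.counts[(g, c)] >= min_cell
    }
    if len(eligible) < 2:
        raise InsufficientSupportError(
            f"{len(eligible)} profile(s) with support >= {min_cell}; need 2"
        )

    if convention == "coverage-rank":
        scores = eligible
    else:  # conditional-rank: P(g|c)
        scores = {c: conditional_frequency(jm, g, c) for c in eligible}

    # descending score; lexicographic on category values breaks ties
    ranked = sorted(scores.items(), key=lambda item: (-item[1], item[0]))
    (c_win, s_win), (c_run, s_run) = ranked[0], ranked[1]
    tied = abs(s_win - s_run) <= _TIE_RTOL * max(abs(s_win), abs(s_run))
    edge = 1.0 if tied else s_win / s_run
    return PollingResult(
        subset=jm.subset,
        outcome="g=1" if g == 1 else "g=0",
        convention=convention,
        winner=Profile(jm.subset, c_win),
        runner_up=Profile(jm.subset, c_run),
        coverage=group_cells[c_win] / m_g,
        edge=edge,
        tied=tied,
        n_effective=jm.n_records,
        n_profiles=len(group_cells),
        winner_score=s_win,
        runner_up_score=s_run,
    )


def poll_dataset(
    ds: CodedDataset,
    subset: Sequence[str],
    outcome: str = "stunted_total",
    convention: str = "coverage-rank",
    min_cell: int = 25,
) -> PollingResult:
    """Convenience wrapper: complete cases, joint distribution, poll."""
    jm = joint_distribution(ds, subset, outcome)
    result = poll(jm, g=1, convention=convention, min_cell=min_cell)
    result.outcome = outcome
    return result
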