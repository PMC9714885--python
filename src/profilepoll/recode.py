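"""Ingest of child-level survey extracts and categorical recoding.

Reads a delimited "children's recode"-style flat file (one row per child
aged 0-59 months, carrying a height-for-age z-score, a sampling weight,
geography codes and raw covariates), applies the standard categorical
codings used throughout the pipeline, and produces a validated
:class:`CodedDataset` — the container every downstream stage consumes.

Coded variables carry string category labels; missing values are ``NaN``.
Sampling weights are used as-is (no normalisation): every downstream
statistic is a ratio and therefore invariant to a global weight rescale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("profilepoll")

#: columns every CodedDataset carries besides coded covariates
CORE_COLUMNS = ("haz", "weight", "division", "district", "cluster_id")

#: recode cut points (documented, config-overridable via the codebook YAML)
EDUCATION_CUTS = (1.0, 6.0)  # years: 0 -> none, 1-5 -> primary, >=6 -> secondary+
BMI_CUTS = (18.5, 25.0)  # kg/m^2 WHO adult bands
HEIGHT_CUT_CM = 145.0
MOTHER_AGE_CUTS = (20.0, 35.0)
AGE_MONTHS_CUT = 12.0  # "child > 1 year" means strictly more than 12 months


@dataclass(frozen=True)
class VariableSpec:
    """One coded covariate: its name, legal categories and provenance."""

    name: str
    categories: tuple[str, ...]
    kind: str = "categorical"  # or "derived-categorical"
    source_column: str | None = None
    coding_rule: str | None = None

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValueError(f"variable {self.name!r}: categories must be non-empty")
        if len(set(self.categories)) != len(self.categories):
            raise ValueError(f"variable {self.name!r}: duplicate categories")


@dataclass(frozen=True)
class ChildRecord:
    """A single child observation: HAZ, survey weight, geography, covariates."""

    haz: float
    weight: float
    division: str
    district: str
    cluster_id: str
    values: dict[str, str | None]


@dataclass
class CodedDataset:
    """Homogeneous collection of child records plus the variable codebook."""

    df: pd.DataFrame
    codebook: list[VariableSpec] = field(default_factory=list)
    survey_label: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in CORE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"dataset missing mandatory column(s): {missing}")

    # -- codebook helpers -------------------------------------------------
    def variable(self, name: str) -> VariableSpec:
        for spec in self.codebook:
            if spec.name == name:
                return spec
        raise KeyError(f"variable {name!r} not in codebook")

    @property
    def variable_names(self) -> list[str]:
        return [spec.name for spec in self.codebook]

    def validate(self) -> None:
        """Check records against the codebook; raise on illegal categories."""
        if len(self.df) == 0:
            raise ValueError("dataset is empty")
        if (self.df["weight"] <= 0).any() or self.df["weight"].isna().any():
            raise ValueError("all weights must be positive")
        haz = self.df["haz"]
        if np.isinf(haz.to_numpy(dtype=float, na_value=np.nan)).any():
            raise ValueError("HAZ must be finite when present")
        for spec in self.codebook:
            if spec.name not in self.df.columns:
                raise ValueError(f"coded column {spec.name!r} absent from data")
            observed = self.df[spec.name].dropna().unique()
            illegal = set(observed) - set(spec.categories)
            if illegal:
                raise ValueError(
                    f"variable {spec.name!r}: illegal categories {sorted(illegal)}"
                )

    # -- record access ----------------------------------------------------
    def record(self, i: int) -> ChildRecord:
        row = self.df.iloc[i]
        values = {
            s.name: (None if pd.isna(row[s.name]) else row[s.name])
            for s in self.codebook
        }
        return ChildRecord(
            haz=float(row["haz"]) if pd.notna(row["haz"]) else float("nan"),
            weight=float(row["weight"]),
            division=str(row["division"]),
            district=str(row["district"]),
            cluster_id=str(row["cluster_id"]),
            values=values,
        )

    def iter_records(self) -> Iterator[ChildRecord]:
        for i in range(len(self.df)):
            yield self.record(i)

    def __len__(self) -> int:
        return len(self.df)

    # -- IO ----------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        cols = [c for c in CORE_COLUMNS if c in self.df.columns]
        cols += [s.name for s in self.codebook]
        extra = [c for c in self.df.columns if c not in cols]
        self.df[cols + extra].to_csv(path, index=False)


def save_codebook(codebook: Sequence[VariableSpec], path: str | Path) -> None:
    payload = [
        {
            "name": s.name,
            "kind": s.kind,
            "categories": list(s.categories),
            "source_column": s.source_column,
            "coding_rule": s.coding_rule,
        }
        for s in codebook
    ]
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_codebook(path: str | Path) -> list[VariableSpec]:
    payload = yaml.safe_load(Path(path).read_text())
    return [
        VariableSpec(
            name=item["name"],
            categories=tuple(item["categories"]),
            kind=item.get("kind", "categorical"),
            source_column=item.get("source_column"),
            coding_rule=item.get("coding_rule"),
        )
        for item in payload
    ]


def read_coded_csv(
    path: str | Path,
    codebook: Sequence[VariableSpec] | None = None,
    codebook_path: str | Path | None = None,
    survey_label: str = "",
) -> CodedDataset:
    """Load an already-coded dataset (the round-trip partner of ``to_csv``)."""
    if codebook is None:
        if codebook_path is None:
            raise ValueError("provide codebook or codebook_path")
        codebook = load_codebook(codebook_path)
    df = pd.read_csv(
        path,
        dtype={"division": str, "district": str, "cluster_id": str},
        float_precision="round_trip",
    )
    for spec in codebook:
        if spec.name in df.columns:
            df[spec.name] = df[spec.name].astype("object")
            df.loc[df[spec.name].isna(), spec.name] = np.nan
    ds = CodedDataset(df=df, codebook=list(codebook), survey_label=survey_label)
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# raw table ingest


def load_children_table(
    path: str | Path,
    column_map: Mapping[str, str],
    dialect: str = "csv",
    missing_marker: str = "",
    survey_label: str = "",
) -> CodedDataset:
    """Read a raw child-level delimited extract into a CodedDataset.

    ``column_map`` maps logical names (``haz``, ``weight``, ``division``,
    ``district`` mandatory; ``cluster_id``, ``age_months`` and the raw
    covariate columns optional) to the file's header names. Children outside
    0-59 months are excluded; rows missing HAZ are retained (flagged missing);
    rows with non-positive weight are rejected and counted.
    """
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    raw = pd.read_csv(path, sep=sep, na_values=[missing_marker], keep_default_na=True)
    for logical in ("haz", "weight", "division", "district"):
        if logical not in column_map:
            raise ValueError(f"column_map must cover mandatory column {logical!r}")
        if column_map[logical] not in raw.columns:
            raise ValueError(
                f"mandatory column {column_map[logical]!r} (for {logical!r}) "
                f"absent from {path}"
            )
    rename = {src: logical for logical, src in column_map.items() if src in raw.columns}
    df = raw.rename(columns=rename)
    n_input = len(df)

    if "cluster_id" not in df.columns:
        df["cluster_id"] = "0"
    for col in ("division", "district", "cluster_id"):
        df[col] = df[col].astype(str)
    df["haz"] = pd.to_numeric(df["haz"], errors="coerce")
    df["weight"] = pd.to_numeric(df["weight"], errors="coerce")

    bad_weight = df["weight"].isna() | (df["weight"] <= 0)
    if bad_weight.any():
        logger.warning("rejected %d record(s) with non-positive weight", int(bad_weight.sum()))
    df = df[~bad_weight]

    if "age_months" in df.columns:
        age = pd.to_numeric(df["age_months"], errors="coerce")
        out_of_range = age.notna() & ((age < 0) | (age > 59))
        if out_of_range.any():
            logger.warning(
                "excluded %d record(s) outside 0-59 months", int(out_of_range.sum())
            )
        df = df[~out_of_range]
        df["age_months"] = pd.to_numeric(df["age_months"], errors="coerce")

    logger.info(
        "loaded %s: %d input rows, %d retained (%d missing HAZ)",
        path, n_input, len(df), int(df["haz"].isna().sum()),
    )
    return CodedDataset(df=df.reset_index(drop=True), codebook=[], survey_label=survey_label)


# ---------------------------------------------------------------------------
# standard codings

def _cut3(x: float, cuts: tuple[float, float], labels: tuple[str, str, str]) -> str:
    if x < cuts[0]:
        return labels[0]
    if x < cuts[1]:
        return labels[1]
    return labels[2]


def _code_education(years: float) -> str:
    return _cut3(years, EDUCATION_CUTS, ("none", "primary", "secondary+"))


def _code_bmi(bmi: float) -> str:
    return _cut3(bmi, BMI_CUTS, ("underweight", "normal", "overweight+"))


def _code_mother_age(age: float) -> str:
    return _cut3(age, MOTHER_AGE_CUTS, ("<20", "20-34", ">=35"))


def _code_child_age(months: float) -> str:
    return ">1y" if months > AGE_MONTHS_CUT else "<=1y"


def _code_height(cm: float) -> str:
    return "<145cm" if cm < HEIGHT_CUT_CM else ">=145cm"


def _code_other_under5(count: float) -> str:
    if count <= 0:
        return "none"
    return "one" if count == 1 else "two+"


_SEX_MAP = {"male": "male", "m": "male", "1": "male",
            "female": "female", "f": "female", "2": "female"}
_DELIVERY_MAP = {
    "home": "home", "respondent's home": "home", "other home": "home",
    "facility": "facility", "hospital": "facility", "clinic": "facility",
    "public facility": "facility", "private facility": "facility",
}
_RESIDENCE_MAP = {"urban": "urban", "1": "urban", "rural": "rural", "2": "rural"}
_WEALTH_LABELS = ("poorest", "poorer", "middle", "richer", "richest")
_WEALTH_MAP = {str(i + 1): lab for i, lab in enumerate(_WEALTH_LABELS)}
_WEALTH_MAP.update({lab: lab for lab in _WEALTH_LABELS})


def _lookup(mapping: Mapping[str, str]) -> Callable[[object], str | None]:
    def code(value: object) -> str | None:
        key = str(value).strip().lower()
        if key.endswith(".0"):  # numeric codes read back as floats
            key = key[:-2]
        return mapping.get(key)

    return code


#: derived variable -> (source logical column, numeric?, coding fn, categories)
STANDARD_CODINGS: dict[str, tuple[str, bool, Callable, tuple[str, ...]]] = {
    "child_age_over_1y": ("age_months", True, _code_child_age, ("<=1y", ">1y")),
    "child_sex": ("sex", False, _lookup(_SEX_MAP), ("male", "female")),
    "mother_education": ("mother_edu_years", True, _code_education,
                         ("none", "primary", "secondary+")),
    "father_education": ("father_edu_years", True, _code_education,
                         ("none", "primary", "secondary+")),
    "mother_bmi": ("mother_bmi", True, _code_bmi,
                   ("underweight", "normal", "overweight+")),
    "mother_height": ("mother_height_cm", True, _code_height, ("<145cm", ">=145cm")),
    "mother_age_at_birth": ("mother_age_at_birth", True, _code_mother_age,
                            ("<20", "20-34", ">=35")),
    "delivery_place": ("delivery_place", False, _lookup(_DELIVERY_MAP),
                       ("home", "facility")),
    "wealth_quintile": ("wealth_quintile", False, _lookup(_WEALTH_MAP), _WEALTH_LABELS),
    "residence": ("residence", False, _lookup(_RESIDENCE_MAP), ("urban", "rural")),
    "other_under5": ("other_under5_count", True, _code_other_under5,
                     ("none", "one", "two+")),
}


def apply_standard_codings(ds: CodedDataset) -> CodedDataset:
    """Derive the standard categorical covariates from raw columns.

    Idempotent: each derived column is a pure function of its raw source, so
    re-running recomputes identical values. Unmappable raw values become
    missing, with a warning count per variable.
    """
    df = ds.df.copy()
    codebook = [s for s in ds.codebook if s.name not in STANDARD_CODINGS]
    for name, (source, numeric, fn, categories) in STANDARD_CODINGS.items():
        if source not in df.columns:
            if name in ds.df.columns:  # already coded upstream; keep as-is
                codebook.append(ds.variable(name) if name in ds.variable_names
                                else VariableSpec(name, categories, "derived-categorical"))
            continue
        observed = set(df[source].dropna().unique())
        if name == source and observed and observed <= set(categories):
            # already coded (e.g. a re-run on derived output); pass through
            codebook.append(
                VariableSpec(name, categories, "derived-categorical", source_column=source)
            )
            continue
        src = pd.to_numeric(df[source], errors="coerce") if numeric else df[source]
        coded = np.full(len(df), np.nan, dtype=object)
        present = src.notna().to_numpy()
        values = src.to_numpy()
        n_unmappable = 0
        for i in np.flatnonzero(present):
            out = fn(values[i])
            if out is None:
                n_unmappable += 1
            else:
                coded[i] = out
        if n_unmappable:
            logger.warning("%s: %d unmappable value(s) set to missing", name, n_unmappable)
        df[name] = coded
        codebook.append(
            VariableSpec(name, categories, "derived-categorical", source_column=source,
                         coding_rule=fn.__name__ if hasattr(fn, "__name__") else name)
        )
    out = CodedDataset(df=df, codebook=codebook, survey_label=ds.survey_label)
    out.validate()
    return out


def complete_cases(ds: CodedDataset, variables: Iterable[str]) -> CodedDataset:
    """Listwise deletion on ``variables`` plus HAZ (per-analysis policy).

    Each analysis calls this with exactly the variables it uses, so every
    polling run keeps its own maximal sample.
    """
    variables = list(variables)
    unknown = set(variables) - set(ds.variable_names)
    if unknown:
        raise KeyError(f"variables not in codebook: {sorted(unknown)}")
    mask = ds.df["haz"].notna()
    for v in variables:
        mask &= ds.df[v].notna()
    kept = ds.df[mask].reset_index(drop=True)
    if len(kept) == 0:
        worst = max(
            variables or ["haz"],
            key=lambda v: int(ds.df[v].isna().sum()) if v in ds.df else 0,
        )
        raise ValueError(
            f"no complete cases; variable with most missingness: {worst!r}"
        )
    logger.info("complete_cases: retained %d/%d records", len(kept), len(ds.df))
    return CodedDataset(df=kept, codebook=list(ds.codebook), survey_label=ds.survey_label)
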