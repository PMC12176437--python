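"""Survey microdata ingestion: dictionary-driven recoding and validity flags.

The pipeline never touches raw questionnaire column names or codes directly.
A :class:`DataDictionary` (a small YAML config) maps each raw column onto a
canonical variable -- 22 dietary-practice markers, 12 sociodemographic /
behavioral covariates and 3 design variables (stratum, PSU, weight) -- so the
same code runs on real PeNSE 2019 microdata and on synthetic tables.

Records with a missing value in any of the 22 scoring inputs are flagged
``absent`` (the survey's code-99 convention) but are *kept in the table with
their design row*: all downstream estimation treats validity as a domain
(subpopulation) indicator so the sampling design, and hence the variance, is
preserved. Covariate missingness never sets a record absent; regressions drop
such records per-analysis (complete case).
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .scoring import MARKER_COLUMNS, UPF_ITEMS, WEEKLY_MARKERS
from .utils import round_half_up

#: Canonical covariates and their category enumerations (first category is
#: the modeling reference unless a regression spec overrides it).
CATEGORIES: dict[str, list[str]] = {
    "sex": ["male", "female"],
    "race": ["white", "black", "yellow", "brown", "indigenous"],
    "maternal_education": [
        "none",
        "incomplete_elementary",
        "complete_elementary",
        "incomplete_high_school",
        "complete_high_school",
        "incomplete_higher",
        "complete_higher",
    ],
    "area": ["urban", "rural"],
    "region": ["North", "Northeast", "Southeast", "South", "Midwest"],
    "school_admin": ["private", "public"],
    "territory": ["capital", "out_of_capital"],
    "laxatives": ["no", "yes"],
    "weight_loss_formula": ["no", "yes"],
    "weight_gain_formula": ["no", "yes"],
    "body_satisfaction": ["very_unhappy", "unhappy", "indifferent", "happy", "very_happy"],
    "self_rated_health": ["very_bad", "bad", "regular", "good", "very_good"],
}

COVARIATE_COLUMNS: tuple[str, ...] = tuple(CATEGORIES)
DESIGN_COLUMNS: tuple[str, ...] = ("stratum", "psu", "weight")
REQUIRED_COLUMNS: tuple[str, ...] = MARKER_COLUMNS + COVARIATE_COLUMNS + DESIGN_COLUMNS


@dataclass(frozen=True)
class VariableDef:
    """Mapping of one raw column onto a canonical variable."""

    name: str
    source: str
    role: str  # marker | covariate | design | id
    dtype: str = "int"  # int | float | category | str
    value_map: Optional[Mapping[str, Union[str, int]]] = None
    missing_codes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.value_map is not None:
            overlap = set(map(str, self.value_map)) & set(self.missing_codes)
            if overlap:
                raise ValueError(
                    f"{self.name}: codes {sorted(overlap)} are both mapped and missing"
                )


@dataclass
class DataDictionary:
    """All variable definitions plus table-level parsing metadata."""

    variables: dict[str, VariableDef]
    delimiter: str = ","

    def __post_init__(self) -> None:
        roles = {"marker", "covariate", "design", "id"}
        for v in self.variables.values():
            if v.role not in roles:
                raise ValueError(f"{v.name}: unknown role {v.role!r}")

    def require_complete(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.variables]
        if missing:
            raise ValueError(f"dictionary missing required canonical variables: {missing}")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "DataDictionary":
        raw = yaml.safe_load(Path(path).read_text())
        variables = {}
        for name, spec in raw["variables"].items():
            variables[name] = VariableDef(
                name=name,
                source=str(spec["source"]),
                role=spec["role"],
                dtype=spec.get("dtype", "int"),
                value_map=spec.get("value_map"),
                missing_codes=frozenset(map(str, spec.get("missing_codes", []))),
            )
        return cls(variables=variables, delimiter=raw.get("delimiter", ","))

    def to_yaml(self, path: Union[str, Path]) -> None:
        out = {"delimiter": self.delimiter, "variables": {}}
        for name, v in self.variables.items():
            spec: dict = {"source": v.source, "role": v.role, "dtype": v.dtype}
            if v.value_map is not None:
                spec["value_map"] = dict(v.value_map)
            if v.missing_codes:
                spec["missing_codes"] = sorted(v.missing_codes)
            out["variables"][name] = spec
        Path(path).write_text(yaml.safe_dump(out, sort_keys=False))


@dataclass(frozen=True)
class RecordError:
    row_id: str
    variable: str
    raw_code: str
    message: str


@dataclass
class LoadResult:
    """Canonical recoded table plus record-level recoding errors."""

    data: pd.DataFrame
    errors: list[RecordError]
    dictionary: DataDictionary


@dataclass(frozen=True)
class ExclusionReport:
    """Accounting of the absent(99) dietary-data exclusion."""

    n_total: int
    n_valid: int

    @property
    def n_absent(self) -> int:
        return self.n_total - self.n_valid

    @property
    def pct_retained(self) -> float:
        return retention_percentage(self.n_valid, self.n_total)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_total": [self.n_total],
                "n_valid": [self.n_valid],
                "n_absent": [self.n_absent],
                "pct_retained": [self.pct_retained],
            }
        )


def retention_percentage(n_valid: int, n_total: int) -> float:
    """Share of the initial sample retained as valid, in %, one decimal
    (half-up), as printed in survey exclusion reports."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round_half_up(100.0 * n_valid / n_total, 1)


def _convert_column(
    raw: pd.Series, vdef: VariableDef, row_ids: pd.Series, errors: list[RecordError]
) -> pd.Series:
    s = raw.astype("string").str.strip()
    missing = s.isin(list(vdef.missing_codes)) | s.isna() | (s == "")
    if vdef.value_map is not None:
        vm = {str(k): v for k, v in vdef.value_map.items()}
        mapped = s.map(vm)
        bad = ~missing & mapped.isna()
        for rid, code in zip(row_ids[bad], s[bad]):
            errors.append(
                RecordError(str(rid), vdef.name, str(code), "unmapped non-missing code")
            )
        values = mapped.where(~missing & ~bad)
    elif vdef.dtype in ("int", "float"):
        numeric = pd.to_numeric(s.where(~missing), errors="coerce")
        bad = ~missing & numeric.isna()
        for rid, code in zip(row_ids[bad], s[bad]):
            errors.append(RecordError(str(rid), vdef.name, str(code), "non-numeric code"))
        values = numeric
    else:
        values = s.where(~missing)

    if vdef.dtype == "int":
        return pd.array(pd.to_numeric(values, errors="coerce"), dtype="Int64")
    if vdef.dtype == "float":
        return pd.to_numeric(values, errors="coerce").astype(float)
    if vdef.dtype == "category":
        cats = CATEGORIES.get(vdef.name)
        return pd.Categorical(values, categories=cats)
    return values.astype("string")


def load_microdata(
    table: Union[str, Path, pd.DataFrame],
    dictionary: Union[str, Path, DataDictionary],
) -> LoadResult:
    """Read and recode a delimited microdata table against a dictionary.

    Raises on structural problems (missing required columns, non-positive
    weights); value-level problems (unmapped codes) are collected per record
    and the offending cell is set missing.
    """
    if not isinstance(dictionary, DataDictionary):
        dictionary = DataDictionary.from_yaml(dictionary)
    dictionary.require_complete()

    if isinstance(table, pd.DataFrame):
        raw = table.astype(str)
    else:
        raw = pd.read_csv(
            table, sep=dictionary.delimiter, dtype=str, keep_default_na=False
        )

    missing_cols = [
        v.source for v in dictionary.variables.values() if v.source not in raw.columns
    ]
    if missing_cols:
        raise ValueError(f"microdata table lacks required source columns: {missing_cols}")

    id_vars = [v for v in dictionary.variables.values() if v.role == "id"]
    if id_vars:
        row_ids = raw[id_vars[0].source].astype(str)
    else:
        row_ids = pd.Series(np.arange(len(raw)).astype(str), index=raw.index)

    errors: list[RecordError] = []
    data = pd.DataFrame(index=raw.index)
    data["id"] = row_ids.to_numpy()
    for name, vdef in dictionary.variables.items():
        if vdef.role == "id":
            continue
        data[name] = _convert_column(raw[vdef.source], vdef, row_ids, errors)

    bad_w = data.index[~(data["weight"] > 0) | data["weight"].isna()]
    if len(bad_w):
        ids = ", ".join(data.loc[bad_w, "id"].head(5))
        raise ValueError(
            f"{len(bad_w)} record(s) with non-positive or missing sampling weight "
            f"(first row ids: {ids})"
        )
    data["stratum"] = data["stratum"].astype(str)
    data["psu"] = data["psu"].astype(str)

    # PSU nesting: a school may not appear in two strata.
    nesting = data.groupby("psu", observed=True)["stratum"].nunique()
    crossed = nesting[nesting > 1]
    if len(crossed):
        raise ValueError(f"PSUs appear in multiple strata: {list(crossed.index[:5])}")

    return LoadResult(data=data, errors=errors, dictionary=dictionary)


def flag_validity(data: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Set ``valid`` per record: False iff any of the 22 scoring inputs is
    missing. Absent records stay in the table (domain estimation)."""
    out = data.copy()
    out["valid"] = out[list(MARKER_COLUMNS)].notna().all(axis=1)
    report = ExclusionReport(n_total=len(out), n_valid=int(out["valid"].sum()))
    return out, report


def summarize_categories(
    data: pd.DataFrame, variables: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Unweighted frequency table per variable, including explicit zero-count
    categories and a Missing row; totals equal the record count."""
    if variables is None:
        variables = [v for v in COVARIATE_COLUMNS if v in data.columns]
    rows = []
    for var in variables:
        col = data[var]
        cats = CATEGORIES.get(var)
        if cats is None:
            cats = sorted(col.dropna().unique())
        counts = col.value_counts(dropna=True)
        for cat in cats:
            rows.append({"variable": var, "category": cat, "count": int(counts.get(cat, 0))})
        rows.append({"variable": var, "category": "(missing)", "count": int(col.isna().sum())})
    return pd.DataFrame(rows, columns=["variable", "category", "count"])


def write_canonical(data: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write the canonical recoded table as CSV (round-trips losslessly)."""
    data.to_csv(path, index=False)


def read_canonical(path: Union[str, Path]) -> pd.DataFrame:
    """Re-load a canonical table written by :func:`write_canonical`."""
    df = pd.read_csv(path, dtype={"id": str, "stratum": str, "psu": str})
    for col in MARKER_COLUMNS:
        if col in df.columns:
            df[col] = pd.array(df[col], dtype="Int64")
    for col, cats in CATEGORIES.items():
        if col in df.columns:
            df[col] = pd.Categorical(df[col], categories=cats)
    if "valid" in df.columns:
        df["valid"] = df["valid"].astype(bool)
    for col in (
        "score_ideal",
        "score_possible",
        "greater_adherence",
    ):
        if col in df.columns:
            df[col] = pd.array(df[col], dtype="Int64")
    return df
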