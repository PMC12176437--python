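"""Adherence scoring against the Brazilian Dietary Guidelines marker index.

The dependent variable of the analysis is a 0-10 score: one point per
dietary-practice component met, built from 22 markers collected in a
PeNSE-style school survey (weekly frequency items, 13 previous-day
ultra-processed-food flags, a screen-eating frequency item). Two threshold
variants of the same ten components are supported:

* ``ideal`` (more restricted): daily beans/fruit/vegetables/breakfast/family
  meals, zero soda, sweets, previous-day ultra-processed items, screen-eating
  and fast-food venue days.
* ``possible`` (less restricted): the same daily staples, but ultra-processed
  exposure tolerated up to 2 days/week and up to 3 previous-day items.

The dichotomous study outcome ("greater adherence") is a possible-variant
total of exactly 10; totals 0-9 form the "some adherence" reference group.
Any missing scoring input invalidates the record (no partial scoring),
mirroring the survey's absent(99) exclusion rule.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

COMPONENT_IDS: tuple[str, ...] = (
    "1.1", "1.2", "1.3", "2.1", "2.2", "2.3", "3.1", "3.2", "3.3", "4.1",
)

#: The 13 previous-day ultra-processed-food indicator columns, in
#: questionnaire order (soda, boxed juice, powdered drink mix, chocolate
#: milk, flavored yogurt, packaged snacks, cookies, industrialized dessert,
#: processed meat, sliced bread, margarine, industrial sauces, instant/frozen
#: ready meals).
UPF_ITEMS: tuple[str, ...] = (
    "upf_soda",
    "upf_boxed_juice",
    "upf_powdered_drink",
    "upf_chocolate_milk",
    "upf_flavored_yogurt",
    "upf_packaged_snacks",
    "upf_cookies",
    "upf_sweet_dessert",
    "upf_processed_meat",
    "upf_sliced_bread",
    "upf_margarine",
    "upf_sauces",
    "upf_instant_noodles",
)

#: Weekly-frequency markers (days/week, 0-7). ``screen_eating_days`` encodes
#: the ordered screen-eating categories on the same 0-7 day scale ("never"=0).
WEEKLY_MARKERS: tuple[str, ...] = (
    "beans_days",
    "fruit_days",
    "vegetables_days",
    "soda_days",
    "sweets_days",
    "breakfast_days",
    "family_meal_days",
    "screen_eating_days",
    "fastfood_days",
)

#: All 22 marker columns whose completeness defines record validity.
MARKER_COLUMNS: tuple[str, ...] = WEEKLY_MARKERS + UPF_ITEMS

VARIANTS: tuple[str, ...] = ("ideal", "possible")


@dataclass(frozen=True)
class ComponentRule:
    """One point-awarding predicate: ``marker <op> threshold``."""

    component_id: str
    variant: str
    marker: str  # canonical marker column, or the derived "upf_sum"
    op: str  # "le" | "ge"
    threshold: int

    def is_met(self, value: Optional[int]) -> Optional[int]:
        """1/0 for the predicate, None when the input is missing."""
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return None
        if self.op == "le":
            return int(value <= self.threshold)
        if self.op == "ge":
            return int(value >= self.threshold)
        raise ValueError(f"unknown operator {self.op!r}")


@dataclass(frozen=True)
class ScoringModel:
    """The ten component rules of one variant."""

    variant: str
    rules: tuple[ComponentRule, ...]

    def __post_init__(self) -> None:
        ids = tuple(r.component_id for r in self.rules)
        if ids != COMPONENT_IDS:
            raise ValueError(
                f"scoring model must cover components {COMPONENT_IDS}, got {ids}"
            )

    def rule(self, component_id: str) -> ComponentRule:
        for r in self.rules:
            if r.component_id == component_id:
                return r
        raise KeyError(component_id)

    def with_upf_threshold(self, threshold: int) -> "ScoringModel":
        """Variant of this model with a different previous-day UPF cutoff.

        The shipped possible-variant cutoff (3 items, the survey's 25th
        percentile) is fixed for reproducibility; this hook supports
        sensitivity runs that recompute the percentile from loaded data.
        """
        rules = tuple(
            ComponentRule(r.component_id, r.variant, r.marker, r.op, int(threshold))
            if r.marker == "upf_sum"
            else r
            for r in self.rules
        )
        return ScoringModel(self.variant, rules)


def _load_rule_table() -> dict[str, dict[str, dict]]:
    text = resources.files("guia_adherence").joinpath("data/scoring_rules.yaml").read_text()
    return yaml.safe_load(text)


def load_models() -> dict[str, ScoringModel]:
    """Load both scoring variants from the shipped rules config."""
    table = _load_rule_table()
    models = {}
    for variant in VARIANTS:
        rules = tuple(
            ComponentRule(cid, variant, spec["marker"], spec["op"], int(spec["threshold"]))
            for cid, spec in sorted(table[variant].items())
        )
        models[variant] = ScoringModel(variant, rules)
    return models


_MODELS = load_models()
IDEAL_MODEL: ScoringModel = _MODELS["ideal"]
POSSIBLE_MODEL: ScoringModel = _MODELS["possible"]


def get_model(variant: str) -> ScoringModel:
    try:
        return _MODELS[variant]
    except KeyError:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


@dataclass(frozen=True)
class MarkerProfile:
    """One respondent's 22 raw dietary-practice responses.

    Day counts are integers in [0, 7] or None; ``upf_yesterday`` is a tuple
    of 13 ternary flags (1=yes, 0=no, None=missing) in :data:`UPF_ITEMS`
    order.
    """

    beans_days: Optional[int]
    fruit_days: Optional[int]
    vegetables_days: Optional[int]
    soda_days: Optional[int]
    sweets_days: Optional[int]
    breakfast_days: Optional[int]
    family_meal_days: Optional[int]
    screen_eating_days: Optional[int]
    fastfood_days: Optional[int]
    upf_yesterday: tuple[Optional[int], ...]

    def __post_init__(self) -> None:
        if len(self.upf_yesterday) != len(UPF_ITEMS):
            raise ValueError(
                f"expected {len(UPF_ITEMS)} previous-day flags, got {len(self.upf_yesterday)}"
            )
        for name in WEEKLY_MARKERS:
            v = getattr(self, name)
            if v is not None and not (0 <= int(v) <= 7):
                raise ValueError(f"{name}={v!r} outside [0, 7]")
        for v in self.upf_yesterday:
            if v is not None and v not in (0, 1):
                raise ValueError(f"previous-day flag {v!r} not in {{0, 1, None}}")

    def marker_value(self, marker: str) -> Optional[int]:
        if marker == "upf_sum":
            return upf_daily_sum(self.upf_yesterday)
        return getattr(self, marker)


@dataclass(frozen=True)
class AdherenceResult:
    """Component indicators and total for one profile under one variant."""

    variant: str
    component_indicators: dict[str, Optional[int]]
    total: Optional[int]
    valid: bool

    @property
    def greater_adherence(self) -> Optional[int]:
        """Dichotomous outcome; defined for the possible variant only."""
        if self.variant != "possible":
            raise ValueError("the dichotomous outcome is defined on the possible variant")
        if not self.valid or self.total is None:
            return None
        return dichotomize(self.total)


def upf_daily_sum(flags: Sequence[Optional[int]]) -> Optional[int]:
    """Count of ultra-processed items consumed the previous day (0-13).

    Returns None if any flag is missing (the sum is a scoring input, so a
    single missing item invalidates it).
    """
    flags = tuple(flags)
    if len(flags) != len(UPF_ITEMS):
        raise ValueError(f"expected {len(UPF_ITEMS)} flags, got {len(flags)}")
    total = 0
    for v in flags:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        total += int(v)
    return total


def score_component(profile: MarkerProfile, rule: ComponentRule) -> Optional[int]:
    """Apply one component rule to a profile; missing inputs propagate."""
    return rule.is_met(profile.marker_value(rule.marker))


def total_score(profile: MarkerProfile, model: ScoringModel) -> AdherenceResult:
    """Score all ten components; any missing component voids the total."""
    indicators = {r.component_id: score_component(profile, r) for r in model.rules}
    if any(v is None for v in indicators.values()):
        return AdherenceResult(model.variant, indicators, total=None, valid=False)
    return AdherenceResult(
        model.variant, indicators, total=sum(indicators.values()), valid=True
    )


def dichotomize(total: int) -> int:
    """Greater adherence (1) iff all ten practices are met; 0-9 is the
    "some adherence" reference category."""
    if not 0 <= total <= 10:
        raise ValueError(f"total {total} outside [0, 10]")
    return int(total == 10)


def upf_sum_frame(df: pd.DataFrame) -> pd.Series:
    """Vectorized previous-day UPF sum over canonical marker columns."""
    block = df[list(UPF_ITEMS)]
    sums = block.sum(axis=1)
    sums[block.isna().any(axis=1)] = pd.NA
    return sums.astype("Int64")


def score_records(df: pd.DataFrame, model: ScoringModel) -> pd.DataFrame:
    """Score a canonical marker table under one variant.

    Returns a frame aligned with ``df`` carrying one indicator column per
    component (``c_1.1`` ...), the ``total`` (nullable) and a ``score_valid``
    flag that is False wherever any scoring input is missing.
    """
    out = pd.DataFrame(index=df.index)
    upf = upf_sum_frame(df)
    for rule in model.rules:
        values = upf if rule.marker == "upf_sum" else df[rule.marker]
        if rule.op == "le":
            met = values <= rule.threshold
        else:
            met = values >= rule.threshold
        out[f"c_{rule.component_id}"] = met.astype("Int64")
    comp = out[[f"c_{cid}" for cid in COMPONENT_IDS]]
    valid = comp.notna().all(axis=1)
    out["total"] = comp.sum(axis=1).where(valid).astype("Int64")
    out["score_valid"] = valid
    return out


def score_both_variants(df: pd.DataFrame) -> pd.DataFrame:
    """Totals under both variants plus the dichotomous outcome.

    Columns: ``score_ideal``, ``score_possible`` (nullable Int64),
    ``score_valid`` and ``greater_adherence`` (1 iff possible total = 10,
    NA for invalid records).
    """
    ideal = score_records(df, IDEAL_MODEL)
    possible = score_records(df, POSSIBLE_MODEL)
    out = pd.DataFrame(index=df.index)
    out["score_ideal"] = ideal["total"]
    out["score_possible"] = possible["total"]
    out["score_valid"] = possible["score_valid"]
    out["greater_adherence"] = (possible["total"] == 10).astype("Int64").where(
        possible["score_valid"]
    )
    return out


def score_distribution(totals: Iterable[Optional[int]]) -> pd.Series:
    """Unweighted counts of valid totals over the full 0-10 support."""
    s = pd.Series(list(totals), dtype="Int64").dropna()
    counts = s.value_counts().reindex(range(11), fill_value=0)
    counts.index.name = "score"
    return counts.astype(int)
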