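"""Synthetic PeNSE-like microdata with known truth.

The generator emulates the structure of Brazil's school-based adolescent
health survey: a stratified two-stage design (strata = region x school-size
class, schools as PSUs, classes within schools), unequal sampling weights,
12 sociodemographic/behavioral covariates and the 22 dietary-practice
markers feeding the adherence score. Every piece of truth -- the latent
adherence propensity, the calibrated full-adherence prevalence, the injected
covariate prevalence ratios -- is stored alongside the data and never read
by the pipeline under test.

Outcome model. Each respondent carries a latent propensity
``eta_i = alpha + sum_k delta[v_k, x_ik] + eps_i`` with ``eps_i`` normal.
Given ``eta_i`` the ten score components are conditionally independent
Bernoulli draws with success probability ``sigmoid(eta_i + offset_c)``
(possible-variant adherence). The shared ``eps`` induces the positive
inter-component dependence needed to make a product-of-ten event ("greater
adherence") reach a realistic ~0.4% while individual components sit at
20-80%. Marker values are then drawn as a two-point mixture consistent
with the component state: the adherent side of the possible-variant
threshold or a uniform draw from the non-adherent side (ideal-variant
adherence arises as the sub-event of the adherent draw hitting the stricter
cutoff, which makes full ideal adherence ~300x rarer -- printing as 0.0%).

Calibration. The intercept ``alpha`` is solved by monotone root finding so
the simulated full-adherence prevalence matches the configured target, on
an independent probe sample; covariate effects are latent shifts solved the
same way so the *realized* prevalence ratio of each category against its
reference matches the requested value. Both use the same probe and are
iterated a few times (effects move the overall prevalence and vice versa).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .association import DEFAULT_REFERENCES
from .microdata import CATEGORIES, DataDictionary, VariableDef
from .scoring import COMPONENT_IDS, UPF_ITEMS, WEEKLY_MARKERS

#: Component marker kinds: how a possible-variant adherent/non-adherent
#: state maps onto raw marker values.
_COMPONENT_MARKERS: dict[str, tuple[str, str]] = {
    "1.1": ("beans_days", "daily"),
    "1.2": ("fruit_days", "daily"),
    "1.3": ("vegetables_days", "daily"),
    "2.1": ("soda_days", "le2"),
    "2.2": ("sweets_days", "le2"),
    "2.3": ("upf_sum", "upf"),
    "3.1": ("breakfast_days", "daily"),
    "3.2": ("family_meal_days", "daily"),
    "3.3": ("screen_eating_days", "le2"),
    "4.1": ("fastfood_days", "le2"),
}

#: Default per-component adherence rates at zero latent propensity
#: (possible variant). Chosen once as survey-plausible marginals: daily
#: beans/breakfast/family meals are common, daily fruit/vegetables are not,
#: and the previous-day UPF cutoff is by construction a lower quartile.
DEFAULT_COMPONENT_RATES: dict[str, float] = {
    "1.1": 0.62,
    "1.2": 0.28,
    "1.3": 0.35,
    "2.1": 0.62,
    "2.2": 0.52,
    "2.3": 0.27,
    "3.1": 0.55,
    "3.2": 0.65,
    "3.3": 0.33,
    "4.1": 0.80,
}

#: Default covariate marginals (region shares are configured separately so
#: they can drive the stratification). Sex/race/region shares follow the
#: source survey's descriptive results; the rest are survey-plausible.
DEFAULT_COVARIATE_MARGINALS: dict[str, dict[str, float]] = {
    "sex": {"male": 0.486, "female": 0.514},
    "race": {"white": 0.36, "black": 0.13, "yellow": 0.04, "brown": 0.45, "indigenous": 0.02},
    "maternal_education": {
        "none": 0.04,
        "incomplete_elementary": 0.17,
        "complete_elementary": 0.09,
        "incomplete_high_school": 0.12,
        "complete_high_school": 0.30,
        "incomplete_higher": 0.08,
        "complete_higher": 0.20,
    },
    "area": {"urban": 0.80, "rural": 0.20},
    "school_admin": {"private": 0.15, "public": 0.85},
    "territory": {"capital": 0.35, "out_of_capital": 0.65},
    "laxatives": {"no": 0.94, "yes": 0.06},
    "weight_loss_formula": {"no": 0.95, "yes": 0.05},
    "weight_gain_formula": {"no": 0.93, "yes": 0.07},
    "body_satisfaction": {
        "very_unhappy": 0.06,
        "unhappy": 0.17,
        "indifferent": 0.13,
        "happy": 0.45,
        "very_happy": 0.19,
    },
    "self_rated_health": {
        "very_bad": 0.02,
        "bad": 0.05,
        "regular": 0.25,
        "good": 0.45,
        "very_good": 0.23,
    },
}

DEFAULT_REGION_SHARES: dict[str, float] = {
    "North": 0.09,
    "Northeast": 0.27,
    "Southeast": 0.402,
    "South": 0.14,
    "Midwest": 0.098,
}

#: Default injected truth: the final-model adjusted prevalence ratios of the
#: source analysis (references: urban, South, capital, very unhappy with
#: body, very bad self-rated health). Behavioral variables its final model
#: excluded are generated null.
DEFAULT_EFFECT_MAP: dict[str, dict[str, float]] = {
    "area": {"rural": 1.91},
    "region": {"Southeast": 1.53, "North": 1.16, "Midwest": 2.29, "Northeast": 1.92},
    "territory": {"out_of_capital": 1.33},
    "body_satisfaction": {
        "unhappy": 0.61,
        "indifferent": 0.92,
        "happy": 1.76,
        "very_happy": 2.72,
    },
    "self_rated_health": {"bad": 6.11, "regular": 1.45, "good": 1.68, "very_good": 3.87},
}

#: Raw source-column names and codes used when emitting survey-style files.
_RAW_MARKER_SOURCES = {name: f"Q{i+1:02d}" for i, name in enumerate(WEEKLY_MARKERS + UPF_ITEMS)}
_RAW_COVARIATE_SOURCES = {name: f"D{i+1:02d}" for i, name in enumerate(CATEGORIES)}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic survey; defaults are the study conditions."""

    seed: int = 0
    schools_total: int = 4000
    region_shares: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_SHARES)
    )
    # size-class -> (share of schools, (min, max) sampled students per school)
    size_classes: dict[str, tuple[float, tuple[int, int]]] = field(
        default_factory=lambda: {"small": (0.5, (20, 30)), "large": (0.5, (45, 55))}
    )
    class_size: int = 30
    covariate_marginals: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_MARGINALS.items()}
    )
    population_total: float = 15_192_972.0
    weight_noise_sd: float = 0.35
    latent_sd: float = 0.7  # sets the inter-component dependence; 0.7 makes the
    # possible-variant score distribution match the published survey's shape
    # while the calibrated full-adherence prevalence stays at the 0.4% target
    component_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPONENT_RATES)
    )
    target_full_adherence: float = 0.004
    effect_map: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EFFECT_MAP.items()}
    )
    marker_missing_rate: float = 0.00176
    covariate_missing_rate: float = 0.01
    probe_size: int = 50_000
    calibration_rel_tol: float = 0.10

    def validate(self) -> None:
        for name, probs in [("region_shares", self.region_shares)] + [
            (v, m) for v, m in self.covariate_marginals.items()
        ]:
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"marginals for {name} sum to {total}, not 1")
        if not 0 < self.target_full_adherence < 1:
            raise ValueError("target prevalence must be in (0, 1)")
        for var, cats in self.effect_map.items():
            if var not in CATEGORIES:
                raise ValueError(f"effect on unknown covariate {var!r}")
            for cat, pr in cats.items():
                valid = CATEGORIES[var]
                if cat not in valid:
                    raise ValueError(f"effect on unknown category {var}={cat!r}")
                if cat == DEFAULT_REFERENCES[var]:
                    raise ValueError(f"cannot inject an effect on the reference {var}={cat!r}")
                if pr <= 0:
                    raise ValueError(f"prevalence ratio must be positive, got {pr}")

    @property
    def component_offsets(self) -> dict[str, float]:
        """Per-component logit offsets at zero latent propensity."""
        return {cid: float(logit(r)) for cid, r in self.component_rates.items()}


@dataclass
class CalibratedModel:
    """Solved latent parameters for one config."""

    alpha: float
    deltas: dict[str, dict[str, float]]  # covariate -> category -> latent shift
    realized_prevalence: float
    realized_prs: dict[str, dict[str, float]]


@dataclass
class SyntheticData:
    """Raw-coded microdata, matching dictionary, and the generating truth."""

    microdata: pd.DataFrame
    dictionary: DataDictionary
    truth: pd.DataFrame  # per-respondent latent propensity etc.
    summary: dict

    def write(self, outdir: Union[str, Path]) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "microdata": outdir / "microdata.csv",
            "dictionary": outdir / "dictionary.yaml",
            "truth": outdir / "truth.csv",
        }
        self.microdata.to_csv(paths["microdata"], sep=";", index=False)
        self.dictionary.to_yaml(paths["dictionary"])
        self.truth.to_csv(paths["truth"], index=False)
        return paths


def _full_adherence_prob(eta: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """P(all ten components met | eta), components independent given eta."""
    return expit(eta[:, None] + offsets[None, :]).prod(axis=1)


def _draw_covariates(
    config: GeneratorConfig, rng: np.random.Generator, n: int, region: Optional[np.ndarray]
) -> dict[str, np.ndarray]:
    cov = {}
    if region is not None:
        cov["region"] = region
    else:
        names = list(config.region_shares)
        p = np.array([config.region_shares[k] for k in names])
        cov["region"] = rng.choice(names, size=n, p=p / p.sum())
    for var, marg in config.covariate_marginals.items():
        names = list(marg)
        p = np.array([marg[k] for k in names])
        cov[var] = rng.choice(names, size=n, p=p / p.sum())
    return cov


def _effect_shift(
    deltas: dict[str, dict[str, float]], cov: dict[str, np.ndarray], n: int
) -> np.ndarray:
    shift = np.zeros(n)
    for var, cats in deltas.items():
        for cat, d in cats.items():
            shift += np.where(cov[var] == cat, d, 0.0)
    return shift


def calibrate_intercept(
    config: GeneratorConfig,
    target: float,
    eta0: np.ndarray,
    offsets: np.ndarray,
) -> float:
    """Solve the latent intercept so mean full-adherence prevalence over the
    probe equals ``target`` (monotone in alpha; bracketed root find)."""
    if not 0 < target < 1:
        raise ValueError("target prevalence must be in (0, 1)")

    def f(alpha: float) -> float:
        return _full_adherence_prob(alpha + eta0, offsets).mean() - target

    lo, hi = -20.0, 20.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("target prevalence not bracketable by the latent intercept")
    alpha = float(brentq(f, lo, hi, xtol=1e-8))
    realized = _full_adherence_prob(alpha + eta0, offsets).mean()
    if abs(realized - target) > config.calibration_rel_tol * target:
        raise ValueError(
            f"intercept calibration off target: {realized:.6f} vs {target:.6f}"
        )
    return alpha


def calibrate(config: GeneratorConfig) -> CalibratedModel:
    """Solve intercept and all effect shifts on an independent probe sample.

    Deterministic given ``config.seed`` (the probe stream is a child of the
    config seed, separate from the data stream used by :func:`generate`).
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    _, probe_ss = ss.spawn(2)
    rng = np.random.default_rng(probe_ss)
    n = config.probe_size
    offsets = np.array([config.component_offsets[c] for c in COMPONENT_IDS])
    eps = rng.normal(0.0, config.latent_sd, n)
    cov = _draw_covariates(config, rng, n, region=None)

    deltas: dict[str, dict[str, float]] = {
        var: {cat: 0.0 for cat in cats} for var, cats in config.effect_map.items()
    }
    alpha = calibrate_intercept(config, config.target_full_adherence, eps, offsets)

    for _ in range(4):  # effects shift the overall prevalence and vice versa
        for var, cats in config.effect_map.items():
            for cat, target_pr in cats.items():
                other = _effect_shift(
                    {v: c for v, c in deltas.items() if v != var}, cov, n
                )
                base = alpha + eps + other  # counterfactual: everyone at reference
                denom = _full_adherence_prob(base, offsets).mean()

                def g(d: float) -> float:
                    return _full_adherence_prob(base + d, offsets).mean() / denom - target_pr

                if g(-8.0) > 0 or g(8.0) < 0:
                    raise ValueError(
                        f"effect {var}={cat} (PR {target_pr}) not attainable"
                    )
                deltas[var][cat] = float(brentq(g, -8.0, 8.0, xtol=1e-8))
        shift = _effect_shift(deltas, cov, n)
        alpha = calibrate_intercept(
            config, config.target_full_adherence, eps + shift, offsets
        )

    shift = _effect_shift(deltas, cov, n)
    q = _full_adherence_prob(alpha + eps + shift, offsets)
    realized_prev = float(q.mean())
    realized_prs: dict[str, dict[str, float]] = {}
    for var, cats in config.effect_map.items():
        realized_prs[var] = {}
        ref = DEFAULT_REFERENCES[var]
        other = _effect_shift({v: c for v, c in deltas.items() if v != var}, cov, n)
        base = alpha + eps + other
        p_ref = _full_adherence_prob(base, offsets).mean()
        for cat in cats:
            realized_prs[var][cat] = float(
                _full_adherence_prob(base + deltas[var][cat], offsets).mean() / p_ref
            )
    return CalibratedModel(alpha, deltas, realized_prev, realized_prs)


def inject_effect(
    config: GeneratorConfig, covariate: str, category: str, true_pr: float
) -> GeneratorConfig:
    """Config with an additional covariate effect (realized PR ~ true_pr)."""
    if covariate not in CATEGORIES:
        raise ValueError(f"unknown covariate {covariate!r}")
    if category not in CATEGORIES[covariate]:
        raise ValueError(f"unknown category {covariate}={category!r}")
    if true_pr <= 0:
        raise ValueError("true_pr must be positive")
    effects = {k: dict(v) for k, v in config.effect_map.items()}
    effects.setdefault(covariate, {})[category] = float(true_pr)
    new = replace(config, effect_map=effects)
    new.validate()
    return new


def _raw_day_codes(values: np.ndarray, missing: np.ndarray) -> np.ndarray:
    """Canonical day count 0-7 -> raw codes "1".."8"; missing -> "99"."""
    raw = (values + 1).astype(int).astype(str)
    raw[missing] = "99"
    return raw


def generate(
    config: GeneratorConfig,
    calibrated: Optional[CalibratedModel] = None,
    output: str = "raw",
) -> SyntheticData:
    """Draw one synthetic survey (byte-identical for a fixed config).

    ``output="raw"`` (default) emits a survey-style coded table that must go
    through :func:`guia_adherence.microdata.load_microdata`; ``"canonical"``
    emits the already-recoded table directly (identical content, used by
    simulation studies that repeat generation many times).
    """
    if output not in ("raw", "canonical"):
        raise ValueError(f"unknown output mode {output!r}")
    config.validate()
    if calibrated is None:
        calibrated = calibrate(config)
    ss = np.random.SeedSequence(config.seed)
    data_ss, _ = ss.spawn(2)
    rng = np.random.default_rng(data_ss)

    # --- design: strata = region x size class, schools as PSUs -------------
    school_rows = []
    for region, share in config.region_shares.items():
        for size_name, (size_share, (lo, hi)) in config.size_classes.items():
            n_sch = max(1, round(config.schools_total * share * size_share))
            sizes = rng.integers(lo, hi + 1, n_sch)
            school_rows.append((region, size_name, sizes))
    region_col, stratum_col, school_col, class_col = [], [], [], []
    school_no = 0
    for region, size_name, sizes in school_rows:
        for sz in sizes:
            school_no += 1
            sid = f"S{school_no:05d}"
            n_classes = max(1, math.ceil(sz / config.class_size))
            for k in range(int(sz)):
                region_col.append(region)
                stratum_col.append(f"{region}|{size_name}")
                school_col.append(sid)
                class_col.append(f"{sid}C{(k % n_classes) + 1}")
    n = len(region_col)
    region_arr = np.array(region_col)
    stratum = np.array(stratum_col)
    school = np.array(school_col)
    class_id = np.array(class_col)

    # weights: region base rate (population share / sampled share), noised
    weights = np.empty(n)
    for region, share in config.region_shares.items():
        sel = region_arr == region
        base = share * config.population_total / sel.sum()
        noise = rng.lognormal(-config.weight_noise_sd**2 / 2, config.weight_noise_sd, sel.sum())
        weights[sel] = base * noise

    # --- covariates and latent propensity ---------------------------------
    cov = _draw_covariates(config, rng, n, region=region_arr)
    eps = rng.normal(0.0, config.latent_sd, n)
    eta = calibrated.alpha + eps + _effect_shift(calibrated.deltas, cov, n)
    offsets = config.component_offsets

    # --- components -> markers --------------------------------------------
    markers: dict[str, np.ndarray] = {}
    adherent: dict[str, np.ndarray] = {}
    for cid in COMPONENT_IDS:
        a = rng.random(n) < expit(eta + offsets[cid])
        adherent[cid] = a
        marker, kind = _COMPONENT_MARKERS[cid]
        if kind == "daily":
            markers[marker] = np.where(a, 7, rng.integers(0, 7, n))
        elif kind == "le2":
            markers[marker] = np.where(a, rng.integers(0, 3, n), rng.integers(3, 8, n))
        else:  # previous-day UPF item count, spread over the 13 flags
            k = np.where(a, rng.integers(0, 4, n), rng.integers(4, 14, n))
            ranks = rng.random((n, len(UPF_ITEMS))).argsort(axis=1).argsort(axis=1)
            flags = ranks < k[:, None]
            for j, item in enumerate(UPF_ITEMS):
                markers[item] = flags[:, j].astype(int)

    # --- missingness (MCAR) ------------------------------------------------
    marker_missing = {
        m: rng.random(n) < config.marker_missing_rate for m in WEEKLY_MARKERS + UPF_ITEMS
    }
    cov_missing = {
        v: rng.random(n) < config.covariate_missing_rate for v in CATEGORIES if v != "region"
    }

    ids = np.char.add("R", np.char.zfill((np.arange(n) + 1).astype(str), 6))
    truth = pd.DataFrame(
        {
            "id": ids,
            "latent_propensity": eta,
            "full_adherence_prob": _full_adherence_prob(
                eta, np.array([offsets[c] for c in COMPONENT_IDS])
            ),
        }
    )
    summary = {
        "alpha": calibrated.alpha,
        "deltas": calibrated.deltas,
        "target_full_adherence": config.target_full_adherence,
        "realized_full_adherence": calibrated.realized_prevalence,
        "target_prs": {k: dict(v) for k, v in config.effect_map.items()},
        "realized_prs": calibrated.realized_prs,
        "n_records": n,
        "n_schools": school_no,
        "n_strata": len(set(stratum_col)),
    }
    dictionary = make_dictionary()

    if output == "canonical":
        table = pd.DataFrame(index=range(n))
        table["id"] = ids
        for m in WEEKLY_MARKERS + UPF_ITEMS:
            table[m] = pd.array(
                np.where(marker_missing[m], np.nan, markers[m]), dtype="Int64"
            )
        for var, cats in CATEGORIES.items():
            values = cov[var].astype(object)
            if var != "region":
                values[cov_missing[var]] = None
            table[var] = pd.Categorical(values, categories=cats)
        table["stratum"] = stratum
        table["psu"] = school
        table["weight"] = weights
        return SyntheticData(
            microdata=table, dictionary=dictionary, truth=truth, summary=summary
        )

    # --- raw coding ---------------------------------------------------------
    raw = pd.DataFrame(index=range(n))
    raw["ID"] = ids
    for m in WEEKLY_MARKERS:
        raw[_RAW_MARKER_SOURCES[m]] = _raw_day_codes(markers[m], marker_missing[m])
    for item in UPF_ITEMS:
        codes = np.where(markers[item] == 1, "1", "2").astype(object)
        codes[marker_missing[item]] = "99"
        raw[_RAW_MARKER_SOURCES[item]] = codes
    for var, cats in CATEGORIES.items():
        idx = {c: str(i + 1) for i, c in enumerate(cats)}
        codes = np.array([idx[c] for c in cov[var]], dtype=object)
        if var != "region":
            codes[cov_missing[var]] = "99"
        raw[_RAW_COVARIATE_SOURCES[var]] = codes
    raw["ESTRATO"] = stratum
    raw["ESCOLA"] = school
    raw["TURMA"] = class_id
    raw["PESO"] = np.round(weights, 6).astype(str)
    return SyntheticData(microdata=raw, dictionary=dictionary, truth=truth, summary=summary)


def make_dictionary() -> DataDictionary:
    """Dictionary mapping the generator's raw coding onto canonical names."""
    variables: dict[str, VariableDef] = {
        "id": VariableDef("id", "ID", "id", dtype="str"),
    }
    day_map = {str(v + 1): v for v in range(8)}
    for m in WEEKLY_MARKERS:
        variables[m] = VariableDef(
            m, _RAW_MARKER_SOURCES[m], "marker", "int", dict(day_map), frozenset({"99"})
        )
    for item in UPF_ITEMS:
        variables[item] = VariableDef(
            item, _RAW_MARKER_SOURCES[item], "marker", "int", {"1": 1, "2": 0}, frozenset({"99"})
        )
    for var, cats in CATEGORIES.items():
        vmap = {str(i + 1): c for i, c in enumerate(cats)}
        variables[var] = VariableDef(
            var, _RAW_COVARIATE_SOURCES[var], "covariate", "category", vmap, frozenset({"99"})
        )
    variables["stratum"] = VariableDef("stratum", "ESTRATO", "design", "str")
    variables["psu"] = VariableDef("psu", "ESCOLA", "design", "str")
    variables["weight"] = VariableDef("weight", "PESO", "design", "float")
    return DataDictionary(variables=variables, delimiter=";")


# ---------------------------------------------------------------------------
# Hand-checkable worked fixture
# ---------------------------------------------------------------------------

# Component order used to build ladder records: first s components met.
_LADDER_ORDER = ("1.1", "1.2", "1.3", "2.1", "2.2", "2.3", "3.1", "3.2", "3.3", "4.1")
# Which components are of the "daily" kind (met-value 7 also satisfies the
# ideal rule; for the other kinds the met-values chosen below satisfy only
# the possible rule).
_DAILY_COMPONENTS = {"1.1", "1.2", "1.3", "3.1", "3.2"}


def _fixture_markers(met: set[str], ideal_strict: bool = False) -> dict[str, int]:
    """Raw marker values for a designed record.

    Met "daily" components get 7 (ideal and possible); met threshold
    components get 2 days (or 3 UPF items) so only the possible rule holds,
    unless ``ideal_strict`` (0 days / 0 items, both rules hold). Unmet
    components get 3 days / 5 days / 6 items respectively.
    """
    values: dict[str, int] = {}
    for cid, (marker, kind) in _COMPONENT_MARKERS.items():
        is_met = cid in met
        if kind == "daily":
            values[marker] = 7 if is_met else 3
        elif kind == "le2":
            values[marker] = (0 if ideal_strict else 2) if is_met else 5
        else:
            values["__upf_count__"] = (0 if ideal_strict else 3) if is_met else 6
    return values


# (record spec, expected possible total, expected ideal total) -- expected
# values written out by hand from the rule table, independent of the
# scoring code. Ladder records 0..10 met components; strict records meet
# ideal thresholds too; extra records vary which components are met.
_FIXTURE_PLAN: list[tuple[dict, int, int]] = (
    [
        ({"met": set(_LADDER_ORDER[:s])}, s, len(set(_LADDER_ORDER[:s]) & _DAILY_COMPONENTS))
        for s in range(11)
    ]
    + [
        ({"met": set(_LADDER_ORDER), "ideal_strict": True}, 10, 10),
        ({"met": {"2.1", "2.2", "2.3", "3.3", "4.1"}}, 5, 0),
        ({"met": {"2.1", "2.2", "2.3", "3.3", "4.1"}, "ideal_strict": True}, 5, 5),
        ({"met": {"1.1", "3.1", "3.2"}}, 3, 3),
        ({"met": {"1.2", "2.3"}}, 2, 1),
        ({"met": {"4.1"}}, 1, 0),
        ({"met": {"4.1"}, "ideal_strict": True}, 1, 1),
        ({"met": {"1.1", "1.2", "1.3"}}, 3, 3),
        ({"met": {"2.3"}}, 1, 0),
        ({"met": {"2.3"}, "ideal_strict": True}, 1, 1),
        ({"met": {"1.1", "2.1", "3.1", "4.1"}}, 4, 2),
        ({"met": {"1.3", "2.2", "3.2", "3.3"}}, 4, 2),
        ({"met": set(_LADDER_ORDER) - {"1.1"}}, 9, 4),
        ({"met": set(_LADDER_ORDER) - {"2.3"}}, 9, 5),
        ({"met": set(_LADDER_ORDER) - {"4.1"}}, 9, 5),
        ({"met": {"1.1", "1.2"}}, 2, 2),
        ({"met": {"2.1", "2.2"}}, 2, 0),
        ({"met": {"3.1", "3.2", "3.3"}}, 3, 2),
        ({"met": {"1.1", "1.2", "1.3", "3.1", "3.2"}}, 5, 5),
        ({"met": {"2.1", "3.3", "4.1"}, "ideal_strict": True}, 3, 3),
        ({"met": set()}, 0, 0),
        ({"met": {"1.1", "1.2", "1.3", "2.1", "2.2", "2.3"}}, 6, 3),
        ({"met": {"2.1", "2.2", "2.3", "3.1", "3.2", "3.3", "4.1"}}, 7, 2),
        ({"met": {"1.1", "1.3", "2.2", "3.2", "4.1"}}, 5, 3),
        ({"met": {"1.2", "2.1", "3.1", "3.3"}}, 4, 2),
        ({"met": set(_LADDER_ORDER[:8])}, 8, 5),
        ({"met": set(_LADDER_ORDER[2:])}, 8, 3),
        ({"met": {"1.1"}}, 1, 1),
        ({"met": {"3.3"}}, 1, 0),
        ({"met": {"3.3"}, "ideal_strict": True}, 1, 1),
        ({"met": {"1.1", "1.2", "1.3", "3.1", "3.2"}, "ideal_strict": True}, 5, 5),
        ({"met": {"2.2", "2.3", "4.1"}}, 3, 0),
        ({"met": set(_LADDER_ORDER[:6])}, 6, 3),
        ({"met": set(_LADDER_ORDER[4:])}, 6, 2),
        ({"met": {"1.2", "1.3"}}, 2, 2),
        ({"met": {"2.1"}}, 1, 0),
        ({"met": {"3.2"}}, 1, 1),
        ({"met": set(_LADDER_ORDER[:9])}, 9, 5),
    ]
)
# hand-check of the ladder ideal totals: met sets grow along _LADDER_ORDER;
# daily components among the first s entries are 1.1,1.2,1.3 (s>=1,2,3) and
# 3.1,3.2 (s>=7,8), so ideal = min(s,3) + max(0, min(s,8) - 6).


def emit_fixture(outdir: Union[str, Path]) -> dict[str, Path]:
    """Write the 50-record worked fixture with its expected-score file.

    Deterministic, no randomness: 49 designed records covering every
    possible-variant score 0-10 (some also meeting the ideal thresholds)
    plus one record with a missing marker that must be flagged absent(99).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dictionary = make_dictionary()

    rows, expected = [], []
    for i, (spec, exp_possible, exp_ideal) in enumerate(_FIXTURE_PLAN):
        rid = f"F{i+1:03d}"
        values = _fixture_markers(set(spec["met"]), spec.get("ideal_strict", False))
        rows.append(_fixture_raw_row(rid, values, missing_marker=None))
        expected.append(
            {
                "id": rid,
                "valid": True,
                "score_possible": exp_possible,
                "score_ideal": exp_ideal,
                "greater_adherence": int(exp_possible == 10),
            }
        )
    # one absent(99) record: all components met but one UPF flag missing
    rid = f"F{len(_FIXTURE_PLAN)+1:03d}"
    values = _fixture_markers(set(_LADDER_ORDER))
    rows.append(_fixture_raw_row(rid, values, missing_marker="upf_margarine"))
    expected.append(
        {
            "id": rid,
            "valid": False,
            "score_possible": "",
            "score_ideal": "",
            "greater_adherence": "",
        }
    )

    microdata = pd.DataFrame(rows)
    expected_df = pd.DataFrame(expected)
    paths = {
        "microdata": outdir / "fixture_microdata.csv",
        "dictionary": outdir / "fixture_dictionary.yaml",
        "expected": outdir / "fixture_expected_scores.csv",
    }
    microdata.to_csv(paths["microdata"], sep=";", index=False)
    dictionary.to_yaml(paths["dictionary"])
    expected_df.to_csv(paths["expected"], index=False)
    return paths


def _fixture_raw_row(
    rid: str, values: dict[str, int], missing_marker: Optional[str]
) -> dict[str, str]:
    row: dict[str, str] = {"ID": rid}
    upf_count = values.pop("__upf_count__")
    for m in WEEKLY_MARKERS:
        row[_RAW_MARKER_SOURCES[m]] = str(values[m] + 1)
    for j, item in enumerate(UPF_ITEMS):
        row[_RAW_MARKER_SOURCES[item]] = "1" if j < upf_count else "2"
    if missing_marker is not None:
        row[_RAW_MARKER_SOURCES[missing_marker]] = "99"
    # fixed covariates/design: two strata with two schools each so the
    # fixture also exercises variance estimation
    i = int(rid[1:])
    for var, cats in CATEGORIES.items():
        row[_RAW_COVARIATE_SOURCES[var]] = str((i % len(cats)) + 1)
    row["ESTRATO"] = "E1" if i <= 26 else "E2"  # schools S01-S02 in E1, S03-S04 in E2
    row["ESCOLA"] = f"S{(i - 1) // 13 + 1:02d}"
    row["TURMA"] = row["ESCOLA"] + "C1"
    row["PESO"] = "100.0" if i % 2 else "150.0"
    return row
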