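"""Prevalence-ratio modeling: survey-weighted Poisson regression with
design-based variance, bivariate screening and backward elimination.

The binary "greater adherence" outcome is regressed on categorical
covariates with a log-link Poisson working model, the standard way to
estimate prevalence ratios directly in cross-sectional data. Point
estimates are the weighted pseudo-maximum-likelihood fit (statsmodels GLM
with the sampling weights as variance weights); the covariance is the
design-based sandwich, linearizing over PSUs within strata exactly as in
:mod:`guia_adherence.survey`::

    V = B G B,   B = (X' diag(w*mu) X)^-1,
    G = sum_h n_h/(n_h-1) sum_c (U_hc - Ubar_h)(U_hc - Ubar_h)'

with ``U_hc`` the PSU totals of the weighted score ``w_i (y_i - mu_i) x_i``.
Records excluded from an analysis (invalid outcome or missing covariate)
contribute zero score but the full design keeps its stratum/PSU structure
(subpopulation estimation). PSU counts ``n_h`` therefore always refer to
the full design.

Per-variable tests are joint Wald tests on the variable's dummy block,
referred to an F distribution with the design degrees of freedom
(``d = PSUs - strata``): ``F = W (d - k + 1)/(d k) ~ F(k, d - k + 1)``,
the convention of design-based survey software; a chi-square reference is
config-selectable. Model selection: covariates with a joint p < 0.20 in
one-covariate fits enter the multivariate model; backward elimination then
repeatedly removes the largest-p variable at or above 0.05, refitting after
each removal, on an estimation sample fixed at the screen-to-multivariate
transition so nested models stay comparable.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .microdata import CATEGORIES
from .survey import SurveyDesign, estimate_proportion
from .utils import pct, round_half_up

#: Modeling reference categories (first category of each enumeration except
#: where the source analysis declares otherwise: South for region).
DEFAULT_REFERENCES: dict[str, str] = {
    **{var: cats[0] for var, cats in CATEGORIES.items()},
    "region": "South",
}


@dataclass(frozen=True)
class RegressionSpec:
    """What to regress and how to select variables."""

    outcome: str = "greater_adherence"
    covariates: tuple[str, ...] = tuple(CATEGORIES)
    references: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_REFERENCES))
    screen_alpha: float = 0.20
    retain_alpha: float = 0.05
    ci_scale: str = "t"  # "t" (design df) | "normal"
    test: str = "f"  # "f" (design-adjusted Wald) | "chi2"
    single_psu: str = "error"

    def __post_init__(self) -> None:
        for a in (self.screen_alpha, self.retain_alpha):
            if not 0 < a < 1:
                raise ValueError(f"alpha {a} outside (0, 1)")
        for var in self.covariates:
            if var not in self.references:
                raise ValueError(f"no reference category declared for {var!r}")


@dataclass(frozen=True)
class PREstimate:
    variable: str
    category: str
    pr: float
    ci_low: float
    ci_high: float
    p_value: float
    stage: str  # bivariate | multivariate
    reference: bool = False


@dataclass(frozen=True)
class VariableTest:
    variable: str
    statistic: float
    k: int
    p_value: float


@dataclass
class PRFit:
    """One fitted prevalence-ratio model."""

    estimates: list[PREstimate]
    tests: dict[str, VariableTest]
    params: np.ndarray
    cov: np.ndarray
    columns: list[str]
    var_blocks: dict[str, list[int]]
    design_df: int
    n_obs: int
    stage: str

    def estimate(self, variable: str, category: str) -> PREstimate:
        for e in self.estimates:
            if e.variable == variable and e.category == category:
                return e
        raise KeyError((variable, category))


@dataclass(frozen=True)
class SelectionStep:
    step: int
    removed: str
    p_at_removal: float
    remaining: tuple[str, ...]


@dataclass
class SelectionTrace:
    steps: list[SelectionStep]
    final_variables: tuple[str, ...]

    def to_records(self) -> list[dict]:
        return [
            {
                "step": s.step,
                "removed": s.removed,
                "p_at_removal": s.p_at_removal,
                "remaining": list(s.remaining),
            }
            for s in self.steps
        ]


def _design_matrix(
    df: pd.DataFrame, covariates: Sequence[str], references: dict[str, str]
) -> tuple[np.ndarray, list[str], dict[str, list[int]], list[tuple[str, str]]]:
    """Intercept + dummy block per covariate, reference level omitted.

    Categories empty in the estimation sample are dropped (with a warning)
    so the matrix stays full rank.
    """
    cols: list[np.ndarray] = [np.ones(len(df))]
    names = ["(intercept)"]
    blocks: dict[str, list[int]] = {}
    labels: list[tuple[str, str]] = []
    for var in covariates:
        ref = references[var]
        observed = df[var].astype(object)
        cats = [c for c in CATEGORIES.get(var, sorted(observed.dropna().unique())) if c != ref]
        idxs = []
        for cat in cats:
            ind = (observed == cat).to_numpy(dtype=float)
            if ind.sum() == 0:
                warnings.warn(
                    f"{var}={cat!r} empty in estimation sample; category dropped",
                    stacklevel=2,
                )
                continue
            idxs.append(len(names))
            names.append(f"{var}[{cat}]")
            labels.append((var, cat))
            cols.append(ind)
        blocks[var] = idxs
    return np.column_stack(cols), names, blocks, labels


def _joint_wald(
    params: np.ndarray,
    cov: np.ndarray,
    idx: Sequence[int],
    design_df: int,
    test: str,
) -> VariableTest:
    idx = list(idx)
    k = len(idx)
    b = params[idx]
    V = cov[np.ix_(idx, idx)]
    W = float(b @ np.linalg.solve(V, b))
    if test == "chi2":
        p = float(stats.chi2.sf(W, k))
        return VariableTest("", W, k, p)
    d = design_df
    if d - k + 1 <= 0:
        raise ValueError("design degrees of freedom too small for the Wald F test")
    F = W * (d - k + 1) / (d * k)
    p = float(stats.f.sf(F, k, d - k + 1))
    return VariableTest("", F, k, p)


def fit_pr_model(
    data: pd.DataFrame,
    design: SurveyDesign,
    spec: RegressionSpec,
    covariates: Optional[Sequence[str]] = None,
    sample_mask: Optional[np.ndarray] = None,
    stage: str = "multivariate",
) -> PRFit:
    """Fit the survey-weighted Poisson PR model for the given covariates.

    ``data`` must align row-for-row with ``design`` and contain the outcome
    (nullable) and covariate columns. The estimation sample is the
    complete-case subset (outcome observed, all covariates observed),
    optionally intersected with ``sample_mask``; the variance always uses
    the full design.
    """
    if covariates is None:
        covariates = list(spec.covariates)
    covariates = list(covariates)
    if len(data) != len(design):
        raise ValueError("data and design are not aligned")

    y_all = data[spec.outcome].to_numpy(dtype="float64", na_value=np.nan)
    mask = ~np.isnan(y_all)
    for var in covariates:
        mask &= data[var].notna().to_numpy()
    if sample_mask is not None:
        mask &= np.asarray(sample_mask, bool)
    if mask.sum() == 0:
        raise ValueError("empty estimation sample")
    sub = data.loc[mask]
    y = y_all[mask]
    if y.min() == y.max():
        raise ValueError("outcome is constant in the estimation sample")
    w = design.weights[mask]

    X, names, blocks, labels = _design_matrix(sub, covariates, spec.references)
    glm = sm.GLM(y, X, family=sm.families.Poisson(), var_weights=w)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rare-outcome fits emit benign domain warnings
        res = glm.fit(tol=1e-10, maxiter=200)
    beta = np.asarray(res.params)
    mu = np.asarray(res.mu)

    # design-based sandwich
    info = X.T @ (X * (w * mu)[:, None])
    bread = np.linalg.inv(info)
    scores = X * (w * (y - mu))[:, None]
    full_scores = np.zeros((len(data), X.shape[1]))
    full_scores[mask] = scores
    meat = design.between_psu_variance(full_scores, single_psu=spec.single_psu)
    cov = bread @ meat @ bread

    d = design.df
    se = np.sqrt(np.diag(cov))
    crit = stats.t.ppf(0.975, d) if spec.ci_scale == "t" else stats.norm.ppf(0.975)

    estimates: list[PREstimate] = []
    tests: dict[str, VariableTest] = {}
    for var in covariates:
        idxs = blocks[var]
        if idxs:
            t = _joint_wald(beta, cov, idxs, d, spec.test)
            tests[var] = VariableTest(var, t.statistic, t.k, t.p_value)
        estimates.append(
            PREstimate(var, spec.references[var], 1.0, np.nan, np.nan, np.nan, stage, True)
        )
    for j, (var, cat) in zip(
        [i for b in blocks.values() for i in b], labels
    ):
        z = beta[j] / se[j]
        p_cat = (
            2 * stats.t.sf(abs(z), d) if spec.ci_scale == "t" else 2 * stats.norm.sf(abs(z))
        )
        estimates.append(
            PREstimate(
                var,
                cat,
                float(np.exp(beta[j])),
                float(np.exp(beta[j] - crit * se[j])),
                float(np.exp(beta[j] + crit * se[j])),
                float(p_cat),
                stage,
            )
        )
    return PRFit(
        estimates=estimates,
        tests=tests,
        params=beta,
        cov=cov,
        columns=names,
        var_blocks=blocks,
        design_df=d,
        n_obs=int(mask.sum()),
        stage=stage,
    )


@dataclass
class ScreenResult:
    included: tuple[str, ...]
    excluded: tuple[str, ...]
    fits: dict[str, PRFit]

    @property
    def p_values(self) -> dict[str, float]:
        return {v: f.tests[v].p_value for v, f in self.fits.items() if v in f.tests}


def bivariate_screen(
    data: pd.DataFrame, design: SurveyDesign, spec: RegressionSpec
) -> ScreenResult:
    """One-covariate fits; a variable passes iff its joint Wald p < 0.20."""
    fits: dict[str, PRFit] = {}
    included, excluded = [], []
    for var in spec.covariates:
        fit = fit_pr_model(data, design, spec, covariates=[var], stage="bivariate")
        fits[var] = fit
        if fit.tests[var].p_value < spec.screen_alpha:
            included.append(var)
        else:
            excluded.append(var)
    return ScreenResult(tuple(included), tuple(excluded), fits)


def backward_eliminate(
    data: pd.DataFrame,
    design: SurveyDesign,
    spec: RegressionSpec,
    included: Sequence[str],
) -> tuple[Optional[PRFit], SelectionTrace]:
    """Backward stepwise removal until every variable's joint p < 0.05.

    The complete-case sample is fixed once, over the full screened set, so
    successive models are fit on identical records. Removal order: largest
    joint p first, one variable per step, refit after each removal. Returns
    (None, trace) when every variable is eliminated.
    """
    current = list(included)
    if not current:
        return None, SelectionTrace(steps=[], final_variables=())
    y_all = data[spec.outcome].to_numpy(dtype="float64", na_value=np.nan)
    fixed_mask = ~np.isnan(y_all)
    for var in current:
        fixed_mask &= data[var].notna().to_numpy()

    steps: list[SelectionStep] = []
    step_no = 0
    while current:
        fit = fit_pr_model(
            data, design, spec, covariates=current, sample_mask=fixed_mask
        )
        worst = max(current, key=lambda v: fit.tests[v].p_value)
        p_worst = fit.tests[worst].p_value
        if p_worst < spec.retain_alpha:
            return fit, SelectionTrace(steps=steps, final_variables=tuple(current))
        step_no += 1
        current.remove(worst)
        steps.append(SelectionStep(step_no, worst, p_worst, tuple(current)))
    return None, SelectionTrace(steps=steps, final_variables=())


def association_report(
    data: pd.DataFrame,
    design: SurveyDesign,
    spec: RegressionSpec,
    screen: ScreenResult,
    final_fit: Optional[PRFit],
    ci_method: str = "logit",
) -> pd.DataFrame:
    """Tidy per-variable/per-category table in the shape of the published
    association table: outcome prevalence for both outcome levels with CIs,
    the screen p, bivariate PRs for screened-in variables and multivariate
    PRs for retained variables (reference rows print "Ref")."""
    y_all = data[spec.outcome].to_numpy(dtype="float64", na_value=np.nan)
    final_vars = tuple(final_fit and [v for v in final_fit.var_blocks] or ())
    rows = []
    for var in spec.covariates:
        screen_p = screen.fits[var].tests[var].p_value
        for cat in CATEGORIES[var]:
            in_cat = (data[var].astype(object) == cat).to_numpy()
            dom = in_cat & ~np.isnan(y_all)
            row: dict = {
                "variable": var,
                "category": cat,
                "screen_p": round(screen_p, 3),
                "is_reference": cat == spec.references[var],
            }
            if dom.sum() > 0:
                greater = estimate_proportion(
                    np.nan_to_num(y_all), design, dom, label=f"{var}={cat}",
                    ci_method=ci_method, single_psu=spec.single_psu,
                )
                row.update(
                    greater_pct=pct(greater.p_hat),
                    greater_ci_low=pct(greater.ci_low),
                    greater_ci_high=pct(greater.ci_high),
                    some_pct=pct(1 - greater.p_hat),
                    some_ci_low=pct(1 - greater.ci_high),
                    some_ci_high=pct(1 - greater.ci_low),
                    n_unweighted=int(dom.sum()),
                )
            for stage, fit in (
                ("bivariate", screen.fits[var] if var in screen.included else None),
                ("multivariate", final_fit if var in final_vars else None),
            ):
                if fit is None:
                    continue
                try:
                    e = fit.estimate(var, cat)
                except KeyError:
                    continue
                prefix = stage
                if e.reference:
                    row[f"{prefix}_pr"] = "Ref"
                else:
                    row[f"{prefix}_pr"] = round_half_up(e.pr, 2)
                    row[f"{prefix}_ci_low"] = round_half_up(e.ci_low, 2)
                    row[f"{prefix}_ci_high"] = round_half_up(e.ci_high, 2)
                    row[f"{prefix}_p"] = round(e.p_value, 3)
            rows.append(row)
    return pd.DataFrame(rows)
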