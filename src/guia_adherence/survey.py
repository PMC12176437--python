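"""Design-based estimation for stratified two-stage cluster samples.

Point estimates are Horvitz-Thompson ratio estimators (weighted means);
variances come from first-order Taylor linearization with schools (PSUs) as
first-stage units, the standard with-replacement approximation used by
survey software for multi-stage designs. Subpopulations (e.g. the records
with valid dietary data) are handled as *domains*: out-of-domain units keep
their place in the design with a zero linearized contribution, so stratum
and PSU counts -- and hence the variance -- reflect the full sample.

For a domain proportion ``p = sum(w*y)/sum(w)`` over domain members, the
linearized value of unit *i* is ``z_i = d_i * w_i * (y_i - p) / N_hat`` with
``N_hat`` the weighted domain size. The variance is the usual stratified
between-PSU form::

    var = sum_h  n_h/(n_h - 1) * sum_c (Z_hc - Zbar_h)^2

where ``Z_hc`` are PSU totals of ``z_i`` and ``n_h`` the number of PSUs in
stratum *h*. Design degrees of freedom follow the PSUs-minus-strata
convention. Confidence intervals for proportions use a logit-transformed
t interval by default (Wald-on-proportion available), truncated to [0, 1].
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .utils import pct


@dataclass(frozen=True)
class DesignInfo:
    n_strata: int
    n_psu: int
    total_weight: float

    @property
    def df(self) -> int:
        """Design degrees of freedom: PSUs minus strata."""
        return self.n_psu - self.n_strata


class SurveyDesign:
    """Stratum, PSU and weight for every record (valid or absent)."""

    def __init__(
        self,
        strata: Sequence,
        psu: Sequence,
        weights: Sequence[float],
    ) -> None:
        self.strata = np.asarray(strata)
        self.psu = np.asarray(psu)
        self.weights = np.asarray(weights, dtype=float)
        if not (len(self.strata) == len(self.psu) == len(self.weights)):
            raise ValueError("strata, psu and weights must have equal length")
        if np.any(~(self.weights > 0)):
            raise ValueError("all sampling weights must be positive")
        # nesting check + integer codes for fast group sums
        pairs = pd.DataFrame({"s": self.strata, "p": self.psu})
        nunique = pairs.groupby("p", observed=True)["s"].nunique()
        if (nunique > 1).any():
            bad = list(nunique.index[nunique > 1][:5])
            raise ValueError(f"PSUs appear in multiple strata: {bad}")
        self._psu_codes, self._psu_index = pd.factorize(
            pd.Series(self.strata).astype(str) + "\x1f" + pd.Series(self.psu).astype(str)
        )
        psu_strata = pd.Series(self.strata).groupby(self._psu_codes).first()
        self._psu_stratum_codes, self._strata_index = pd.factorize(psu_strata)

    def __len__(self) -> int:
        return len(self.weights)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurveyDesign":
        return cls(df["stratum"].to_numpy(), df["psu"].to_numpy(), df["weight"].to_numpy())

    @property
    def n_psu(self) -> int:
        return len(self._psu_index)

    @property
    def n_strata(self) -> int:
        return len(self._strata_index)

    @property
    def df(self) -> int:
        return self.n_psu - self.n_strata

    def info(self) -> DesignInfo:
        return DesignInfo(self.n_strata, self.n_psu, float(self.weights.sum()))

    def psu_totals(self, values: np.ndarray) -> np.ndarray:
        """Sum ``values`` (per record, possibly a 2-D row block) over PSUs.

        Every PSU of the design appears, including PSUs whose members all
        carry zeros (out-of-domain): they still anchor the variance.
        """
        values = np.asarray(values, dtype=float)
        if values.ndim == 1:
            return np.bincount(self._psu_codes, weights=values, minlength=self.n_psu)
        out = np.empty((self.n_psu, values.shape[1]))
        for j in range(values.shape[1]):
            out[:, j] = np.bincount(
                self._psu_codes, weights=values[:, j], minlength=self.n_psu
            )
        return out

    def between_psu_variance(
        self, values: np.ndarray, single_psu: str = "error"
    ) -> np.ndarray:
        """Stratified between-PSU variance of the total of ``values``.

        ``values`` may be (n,) or (n, k); returns a scalar or a (k, k)
        covariance. ``single_psu`` selects the policy for strata with one
        PSU: ``error`` (default), ``certainty`` (contribute zero) or
        ``collapse`` (pool all singleton strata into one).
        """
        totals = self.psu_totals(values)
        one_dim = totals.ndim == 1
        if one_dim:
            totals = totals[:, None]
        strat = self._psu_stratum_codes.copy()
        counts = np.bincount(strat)
        singletons = np.flatnonzero(counts == 1)
        if len(singletons):
            if single_psu == "error":
                names = [str(self._strata_index[i]) for i in singletons[:5]]
                raise ValueError(
                    f"{len(singletons)} stratum/strata with a single PSU "
                    f"(e.g. {names}); pass single_psu='certainty' or 'collapse'"
                )
            if single_psu == "certainty":
                keep = ~np.isin(strat, singletons)
                totals, strat = totals[keep], strat[keep]
                strat = pd.factorize(strat)[0]
                counts = np.bincount(strat) if len(strat) else np.array([], dtype=int)
            elif single_psu == "collapse":
                merged = max(strat) + 1 if len(strat) else 0
                strat = np.where(np.isin(strat, singletons), merged, strat)
                strat = pd.factorize(strat)[0]
                counts = np.bincount(strat)
                if (counts == 1).any():
                    raise ValueError("collapse left a singleton stratum")
            else:
                raise ValueError(f"unknown single_psu policy {single_psu!r}")
        k = totals.shape[1]
        var = np.zeros((k, k))
        for h in range(len(counts)):
            sel = totals[strat == h]
            n_h = sel.shape[0]
            dev = sel - sel.mean(axis=0)
            var += n_h / (n_h - 1) * dev.T @ dev
        return var[0, 0] if one_dim else var


def weighted_proportion(
    y: Sequence[float],
    design: SurveyDesign,
    domain: Optional[Sequence[bool]] = None,
) -> float:
    """Design-weighted domain proportion ``sum(w*y)/sum(w)``."""
    y = np.asarray(y, dtype=float)
    d = np.ones(len(design), bool) if domain is None else np.asarray(domain, bool)
    wd = design.weights * d
    denom = wd.sum()
    if denom <= 0:
        raise ValueError("empty domain: no weight in the requested subpopulation")
    return float((wd * np.where(d, y, 0.0)).sum() / denom)


def linearized_se(
    y: Sequence[float],
    design: SurveyDesign,
    domain: Optional[Sequence[bool]] = None,
    single_psu: str = "error",
) -> float:
    """Taylor-linearized standard error of the domain proportion."""
    y = np.asarray(y, dtype=float)
    d = np.ones(len(design), bool) if domain is None else np.asarray(domain, bool)
    p = weighted_proportion(y, design, d)
    n_hat = (design.weights * d).sum()
    z = np.where(d, design.weights * (np.where(d, y, 0.0) - p), 0.0) / n_hat
    var = design.between_psu_variance(z, single_psu=single_psu)
    return float(np.sqrt(max(var, 0.0)))


def proportion_ci(
    p_hat: float,
    se: float,
    df: int,
    level: float = 0.95,
    method: str = "logit",
    n_eff: Optional[float] = None,
) -> tuple[float, float]:
    """Confidence interval for a proportion from a design-based SE.

    ``logit`` (default): t interval on the logit scale, back-transformed --
    the survey-software convention that keeps limits inside (0, 1) even for
    rare outcomes. ``wald``: symmetric interval truncated to [0, 1].
    Degenerate ``p_hat`` of exactly 0 or 1 (where the linearized SE is 0)
    gets a one-sided interval built from the nearest representable
    proportion ``1/(2*n_eff)``.
    """
    if df <= 0:
        raise ValueError("design degrees of freedom must be positive")
    if not 0 <= p_hat <= 1:
        raise ValueError("p_hat outside [0, 1]")
    t = stats.t.ppf(0.5 + level / 2.0, df)
    if p_hat in (0.0, 1.0):
        if n_eff is None or n_eff <= 0:
            raise ValueError("degenerate proportion needs n_eff for a one-sided bound")
        eps = 0.5 / n_eff
        p_adj = eps if p_hat == 0.0 else 1.0 - eps
        se_adj = np.sqrt(p_adj * (1 - p_adj) / n_eff)
        lo, hi = proportion_ci(p_adj, se_adj, df, level, method="logit")
        return (0.0, hi) if p_hat == 0.0 else (lo, 1.0)
    if se == 0.0:
        return (p_hat, p_hat)
    if method == "wald":
        return (max(0.0, p_hat - t * se), min(1.0, p_hat + t * se))
    if method != "logit":
        raise ValueError(f"unknown CI method {method!r}")
    logit = np.log(p_hat / (1 - p_hat))
    se_l = se / (p_hat * (1 - p_hat))
    lo, hi = logit - t * se_l, logit + t * se_l
    expit = lambda x: 1.0 / (1.0 + np.exp(-x))
    return (float(expit(lo)), float(expit(hi)))


@dataclass(frozen=True)
class PrevalenceEstimate:
    """One design-based prevalence with its interval and sample sizes."""

    domain: str
    level: Union[int, str]
    p_hat: float
    se: float
    ci_low: float
    ci_high: float
    n_unweighted: int
    n_weighted: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.p_hat <= 1):
            raise ValueError("p_hat outside [0, 1]")
        if not (self.ci_low - 1e-12 <= self.p_hat <= self.ci_high + 1e-12):
            raise ValueError("point estimate outside its interval")


def estimate_proportion(
    y: Sequence[float],
    design: SurveyDesign,
    domain: Optional[Sequence[bool]] = None,
    label: str = "all",
    level_label: Union[int, str] = "",
    ci_method: str = "logit",
    single_psu: str = "error",
) -> PrevalenceEstimate:
    """Full design-based estimate (point, SE, CI) for one indicator."""
    d = np.ones(len(design), bool) if domain is None else np.asarray(domain, bool)
    p = weighted_proportion(y, design, d)
    se = linearized_se(y, design, d, single_psu=single_psu)
    n_unw = int(d.sum())
    ci = proportion_ci(p, se, design.df, method=ci_method, n_eff=n_unw)
    return PrevalenceEstimate(
        domain=label,
        level=level_label,
        p_hat=p,
        se=se,
        ci_low=ci[0],
        ci_high=ci[1],
        n_unweighted=n_unw,
        n_weighted=float((design.weights * d).sum()),
        degenerate=p in (0.0, 1.0),
    )


def score_prevalence_table(
    scored: pd.DataFrame,
    design: SurveyDesign,
    variants: Sequence[str] = ("ideal", "possible"),
    ci_method: str = "logit",
    single_psu: str = "error",
) -> pd.DataFrame:
    """Weighted prevalence of each score level 0-10, per variant.

    ``scored`` must align with the design and carry ``score_<variant>``
    columns plus ``valid``; the valid records form the estimation domain
    while absent records stay in the design. Within a variant the
    (pre-rounding) prevalences sum to 1.
    """
    if len(scored) != len(design):
        raise ValueError("scored table and design are not aligned")
    valid = scored["valid"].to_numpy(dtype=bool)
    rows = []
    for variant in variants:
        totals = scored[f"score_{variant}"].to_numpy(dtype="float64", na_value=np.nan)
        for level in range(11):
            y = (totals == level).astype(float)
            est = estimate_proportion(
                y,
                design,
                domain=valid,
                label=f"valid:{variant}",
                level_label=level,
                ci_method=ci_method,
                single_psu=single_psu,
            )
            rows.append(
                {
                    "variant": variant,
                    "score": level,
                    "prevalence": est.p_hat,
                    "se": est.se,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "pct": pct(est.p_hat),
                    "pct_ci_low": pct(est.ci_low),
                    "pct_ci_high": pct(est.ci_high),
                    "n_unweighted": est.n_unweighted,
                }
            )
    table = pd.DataFrame(rows)
    for variant in variants:
        s = table.loc[table["variant"] == variant, "prevalence"].sum()
        if abs(s - 1.0) > 1e-9:
            raise AssertionError(f"{variant}: level prevalences sum to {s}, not 1")
    return table
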