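"""Linear modelling of genetic diversity: transforms, collinearity
screening, OLS with confidence intervals, AIC-stepwise selection with
forced terms, hierarchical partitioning of explained variance, and the
marine-vs-freshwater latitude-adjusted comparison.

Models are ordinary least squares on a log-transformed, standardized
response.  Terms are given as formula fragments (e.g. ``"temperature"`` or
``"C(region)"``); categorical factors enter and leave stepwise selection as
whole blocks.  Hierarchical partitioning decomposes the full model's R^2
into per-predictor independent contributions by averaging the R^2 increase
each predictor brings over all orderings of the predictors.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from collections.abc import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats


@dataclasses.dataclass
class ModelResult:
    """Fitted linear-model artefacts."""

    params: pd.Series
    conf_int: pd.DataFrame  # columns: low, high
    aic: float
    r2: float
    adj_r2: float
    terms: list[str]
    residuals: np.ndarray
    nobs: int

    def coef(self, name: str) -> float:
        return float(self.params[name])


@dataclasses.dataclass(frozen=True)
class HierPartResult:
    """Independent/joint contributions per predictor.

    ``independent[j]`` is predictor j's average R^2 increase over all
    orderings; ``joint[j] = R^2(j alone) - independent[j]``; relative
    variance re-expresses the independent contributions as percentages.
    """

    terms: list[str]
    independent: np.ndarray
    joint: np.ndarray
    relative_pct: np.ndarray
    full_r2: float


def transform_response(gd: np.ndarray, epsilon: float | None = None) -> np.ndarray:
    """log(GD + eps), centred and scaled to unit variance (ddof=1).

    ``eps`` defaults to half the smallest positive GD, so zero-diversity
    cells stay in the analysis on the log scale.
    """
    gd = np.asarray(gd, dtype=float)
    if np.any(gd < 0):
        raise ValueError("GD must be non-negative")
    positive = gd[gd > 0]
    if positive.size == 0:
        raise ValueError("all GD values are zero; no scale for the log transform")
    if epsilon is None:
        epsilon = float(positive.min()) / 2.0
    logged = np.log(gd + epsilon)
    sd = logged.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance after log transform")
    return (logged - logged.mean()) / sd


def standardize(x: np.ndarray) -> np.ndarray:
    """Centre and scale to unit variance (ddof=1)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance column")
    return (x - x.mean()) / sd


def vif_screen(
    predictors: pd.DataFrame, threshold: float = 5.0
) -> tuple[list[str], pd.DataFrame]:
    """Iteratively drop the highest-VIF column while any VIF > threshold.

    ``VIF_j = 1 / (1 - R^2_j)`` from regressing column j on the others
    (with intercept).  Perfectly collinear columns surface as infinite VIF
    and are dropped first; ties break by column order.  Returns the
    retained column names and a per-iteration report.
    """
    cols = list(predictors.columns)
    report_rows = []
    while len(cols) > 1:
        vifs = {}
        x = predictors[cols].to_numpy(dtype=float)
        for j, name in enumerate(cols):
            others = np.column_stack(
                [np.ones(len(x))] + [x[:, m] for m in range(len(cols)) if m != j]
            )
            yj = x[:, j]
            beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
            resid = yj - others @ beta
            tss = float(np.sum((yj - yj.mean()) ** 2))
            if tss == 0:
                vifs[name] = np.inf
                continue
            r2 = 1.0 - float(resid @ resid) / tss
            vifs[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        worst = max(cols, key=lambda c: (vifs[c], -cols.index(c)))
        if vifs[worst] <= threshold:
            break
        report_rows.append({"dropped": worst, "vif": vifs[worst]})
        cols.remove(worst)
    return cols, pd.DataFrame(report_rows, columns=["dropped", "vif"])


def _formula(response: str, terms: Sequence[str]) -> str:
    rhs = " + ".join(terms) if terms else "1"
    return f"{response} ~ {rhs}"


def _aic_gaussian(fit) -> float:
    """AIC with k = slope/intercept parameters + 1 for the error variance."""
    return float(-2.0 * fit.llf + 2.0 * (fit.df_model + 2.0))


def fit_lm(data: pd.DataFrame, response: str, terms: Sequence[str]) -> ModelResult:
    """OLS fit of ``response ~ terms`` with 95% confidence intervals.

    Confidence intervals come from the t distribution on the residual
    degrees of freedom; AIC uses the Gaussian log-likelihood with the error
    variance counted as an estimated parameter.
    """
    terms = list(terms)
    n = len(data)
    fit = smf.ols(_formula(response, terms), data=data).fit()
    if n <= fit.df_model + 1:
        raise ValueError("more parameters than observations")
    ci = fit.conf_int(alpha=0.05)
    ci.columns = ["low", "high"]
    return ModelResult(
        params=fit.params,
        conf_int=ci,
        aic=_aic_gaussian(fit),
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        terms=terms,
        residuals=np.asarray(fit.resid),
        nobs=int(fit.nobs),
    )


def step_aic(
    data: pd.DataFrame,
    response: str,
    terms: Sequence[str],
    forced: Sequence[str] = (),
) -> ModelResult:
    """Backward-forward stepwise selection minimizing AIC.

    Starts from the full model; at each step considers dropping any
    non-forced term or re-adding any removed term and takes the move with
    the lowest AIC, stopping when no move improves it.  Forced terms are
    never dropped; categorical factors (``C(...)`` terms) move as blocks.
    Deterministic: ties break toward the earlier candidate move.
    """
    terms = list(terms)
    forced = list(forced)
    unknown = [t for t in forced if t not in terms]
    if unknown:
        raise ValueError(f"forced terms not in term list: {unknown}")
    current = list(terms)
    best = fit_lm(data, response, current)
    while True:
        moves: list[tuple[float, list[str]]] = []
        for t in current:
            if t in forced:
                continue
            cand = [c for c in current if c != t]
            moves.append((fit_lm(data, response, cand).aic, cand))
        for t in terms:
            if t not in current:
                cand = current + [t]
                moves.append((fit_lm(data, response, cand).aic, cand))
        if not moves:
            break
        best_aic, best_terms = min(moves, key=lambda m: m[0])
        if best_aic < best.aic - 1e-10:
            current = best_terms
            best = fit_lm(data, response, current)
        else:
            break
    return best


def _subset_r2(data: pd.DataFrame, response: str, terms: tuple[str, ...]) -> float:
    if not terms:
        return 0.0
    return float(smf.ols(_formula(response, terms), data=data).fit().rsquared)


def hier_part(
    data: pd.DataFrame, response: str, terms: Sequence[str]
) -> HierPartResult:
    """Hierarchical partitioning of R^2 over all 2^k predictor subsets.

    The independent contribution of predictor j is its R^2 increase when
    added to a subset S of the other predictors, averaged over orderings —
    equivalently a sum over subsets weighted by ``|S|! (k-|S|-1)! / k!``.
    Refuses k > 12 (2^k subset fits).
    """
    terms = list(terms)
    k = len(terms)
    if k == 0:
        raise ValueError("no predictors")
    if k > 12:
        raise ValueError(f"hierarchical partitioning limited to 12 predictors, got {k}")
    r2: dict[frozenset, float] = {}
    for r in range(k + 1):
        for subset in itertools.combinations(terms, r):
            r2[frozenset(subset)] = _subset_r2(data, response, subset)
    independent = np.zeros(k)
    fact = math.factorial
    for j, t in enumerate(terms):
        others = [u for u in terms if u != t]
        total = 0.0
        for r in range(k):
            weight = fact(r) * fact(k - r - 1) / fact(k)
            for subset in itertools.combinations(others, r):
                s = frozenset(subset)
                total += weight * (r2[s | {t}] - r2[s])
        independent[j] = total
    joint = np.array([r2[frozenset({t})] for t in terms]) - independent
    total_i = independent.sum()
    relative = 100.0 * independent / total_i if total_i > 0 else np.full(k, np.nan)
    return HierPartResult(
        terms=terms,
        independent=independent,
        joint=joint,
        relative_pct=relative,
        full_r2=r2[frozenset(terms)],
    )


def habitat_latitude_model(
    data: pd.DataFrame,
    response: str = "gd",
    latitude: str = "latitude",
    habitat: str = "habitat",
    transform: bool = True,
) -> tuple[ModelResult, HierPartResult]:
    """Latitude-adjusted comparison of diversity between two habitats.

    Fits ``transformed(response) ~ latitude + habitat`` on the pooled cell
    table, where ``habitat`` is a 0/1 indicator (marine = 1 convention).
    Returns the fit (the habitat coefficient and its CI are the quantity of
    interest) and the hierarchical partition giving the habitat factor's
    partial variance.
    """
    levels = set(pd.unique(data[habitat]))
    if len(levels) < 2:
        raise ValueError("both habitats must be present")
    df = data[[response, latitude, habitat]].copy()
    if transform:
        df["_resp"] = transform_response(df[response].to_numpy())
    else:
        df["_resp"] = df[response]
    fit = fit_lm(df, "_resp", [latitude, habitat])
    hp = hier_part(df, "_resp", [latitude, habitat])
    return fit, hp


def region_rank_test(
    values: np.ndarray, regions: np.ndarray, focal: str
) -> tuple[float, float]:
    """One-region-vs-rest Wilcoxon (Mann-Whitney) rank-sum comparison.

    Returns the U statistic and two-sided p-value for the focal region's
    values against all other regions pooled.
    """
    values = np.asarray(values, dtype=float)
    regions = np.asarray(regions)
    in_focal = regions == focal
    if in_focal.sum() == 0 or (~in_focal).sum() == 0:
        raise ValueError(f"region {focal!r} or its complement is empty")
    res = stats.mannwhitneyu(values[in_focal], values[~in_focal], alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
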