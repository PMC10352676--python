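"""Statistical layer: Pearson correlations, simple/multiple linear models of
photosynthetic capacity on leaf traits, random-forest permutation importance
(%IncMSE), and seasonal-change summaries.

The linear models regress Vcmax25 (or Jmax25) on leaf nitrogen, chlorophyll
and carotenoid content by ordinary least squares; significance is the
overall ANOVA F-test.  Predictor importance uses a bagged regression-tree
ensemble with out-of-bag permutation: for each tree, the OOB mean squared
error is recomputed after permuting one predictor's OOB values, and the
percent increase is averaged over trees.  A predictor that carries no
information about the response has %IncMSE near zero.

Percent changes between sampling days are reported under BOTH conventions,
(later - earlier)/earlier and (later - earlier)/later, explicitly labelled:
a decline can exceed 100% only under the second, and seasonal narratives in
the field literature mix the two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "CorrelationResult",
    "RegressionModel",
    "ImportanceTable",
    "RFSettings",
    "SeasonalSummary",
    "TraitChange",
    "pearson_r",
    "correlation_matrix",
    "significance_stars",
    "fit_linear_model",
    "model_suite",
    "rf_importance",
    "seasonal_changes",
]


@dataclass(frozen=True)
class CorrelationResult:
    x_label: str
    y_label: str
    r: float
    n: int
    p_value: float


def significance_stars(p: float) -> str:
    """Conventional star annotation: *** <0.001, ** <0.01, * <0.05."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pearson_r(x, y, x_label: str = "x", y_label: str = "y") -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-test p-value.

    Computed by direct summation of centred cross-products,
    r = Σ(x-x̄)(y-ȳ) / sqrt(Σ(x-x̄)² Σ(y-ȳ)²), then
    t = r·sqrt((n-2)/(1-r²)) on n-2 degrees of freedom.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-d and of equal length")
    n = len(xa)
    if n < 3:
        raise ValueError("need at least 3 observations")
    dx = xa - xa.mean()
    dy = ya - ya.mean()
    sxx = float(np.sum(dx * dx))
    syy = float(np.sum(dy * dy))
    if sxx == 0.0:
        raise ValueError(f"series {x_label!r} has zero variance")
    if syy == 0.0:
        raise ValueError(f"series {y_label!r} has zero variance")
    r = float(np.sum(dx * dy) / math.sqrt(sxx * syy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return CorrelationResult(x_label=x_label, y_label=y_label, r=r, n=n, p_value=p)


def correlation_matrix(
    samples: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, dict[tuple[str, str], CorrelationResult]]:
    """All pairwise correlations among ``columns`` (complete cases).

    Returns the symmetric r matrix (unit diagonal) and the per-pair results
    keyed by (row, column) label.
    """
    cols = columns if columns is not None else list(samples.columns)
    data = samples[cols].dropna()
    if len(data) < 3:
        raise ValueError("need at least 3 complete rows")
    rmat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    results: dict[tuple[str, str], CorrelationResult] = {}
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            res = pearson_r(data[a], data[b], a, b)
            rmat.loc[a, b] = rmat.loc[b, a] = res.r
            results[(a, b)] = results[(b, a)] = res
    return rmat, results


@dataclass
class RegressionModel:
    """An OLS fit of a capacity on leaf traits, with ANOVA significance."""

    response: str
    predictors: list[str]
    coefficients: dict[str, float]  # includes "intercept"
    r_squared: float
    anova_f: float
    anova_p: float
    n: int
    units: dict[str, str] = field(default_factory=dict)

    def predict(self, samples: pd.DataFrame) -> np.ndarray:
        out = np.full(len(samples), self.coefficients["intercept"])
        for p in self.predictors:
            out = out + self.coefficients[p] * samples[p].to_numpy(float)
        return out


#: Units of the canonical model predictors; nitrogen enters the regression
#: in g m⁻² (its coefficient magnitude is meaningful only at that scale),
#: pigments in µg cm⁻².
DEFAULT_UNITS = {
    "n_area_g_m2": "g m-2",
    "chl_area_ug_cm2": "ug cm-2",
    "car_area_ug_cm2": "ug cm-2",
    "sla_cm2_g": "cm2 g-1",
    "vcmax25": "umol m-2 s-1",
    "jmax25": "umol m-2 s-1",
}


def fit_linear_model(
    samples: pd.DataFrame,
    response: str,
    predictors: list[str],
    units: dict[str, str] | None = None,
) -> RegressionModel:
    """Ordinary least squares of ``response`` on ``predictors`` (complete cases)."""
    data = samples[[response, *predictors]].dropna()
    if len(data) < len(predictors) + 2:
        raise ValueError(
            f"{len(data)} complete rows is too few for {len(predictors)} predictors"
        )
    x = sm.add_constant(data[predictors].to_numpy(float))
    if np.linalg.matrix_rank(x) < x.shape[1]:
        corr = data[predictors].corr().abs()
        collinear = [
            (a, b)
            for i, a in enumerate(predictors)
            for b in predictors[i + 1 :]
            if corr.loc[a, b] > 1 - 1e-10
        ]
        raise ValueError(f"rank-deficient design; collinear predictors: {collinear or predictors}")
    fit = sm.OLS(data[response].to_numpy(float), x).fit()
    coefs = {"intercept": float(fit.params[0])}
    coefs.update({p: float(c) for p, c in zip(predictors, fit.params[1:])})
    unit_meta = {k: (units or DEFAULT_UNITS).get(k, "?") for k in [response, *predictors]}
    return RegressionModel(
        response=response,
        predictors=list(predictors),
        coefficients=coefs,
        r_squared=float(fit.rsquared),
        anova_f=float(fit.fvalue),
        anova_p=float(fit.f_pvalue),
        n=int(fit.nobs),
        units=unit_meta,
    )


def model_suite(
    samples: pd.DataFrame,
    n_col: str = "n_area_g_m2",
    chl_col: str = "chl_area_ug_cm2",
    car_col: str = "car_area_ug_cm2",
) -> list[RegressionModel]:
    """The full battery of capacity~trait models: for each capacity
    (Vcmax25, Jmax25) the three single-trait models, plus the four
    multi-trait Vcmax25 models (N+Chl, Chl+Car, N+Car, N+Chl+Car)."""
    models = []
    for response in ("vcmax25", "jmax25"):
        for pred in (n_col, chl_col, car_col):
            models.append(fit_linear_model(samples, response, [pred]))
    for preds in (
        [n_col, chl_col],
        [chl_col, car_col],
        [n_col, car_col],
        [n_col, chl_col, car_col],
    ):
        models.append(fit_linear_model(samples, "vcmax25", preds))
    return models


@dataclass(frozen=True)
class RFSettings:
    """Bagged-tree ensemble settings for permutation importance."""

    n_trees: int = 500
    max_features: int | None = None  # default ceil(p/3)
    seed: int = 0
    min_rows: int = 10


@dataclass
class ImportanceTable:
    """%IncMSE per predictor from out-of-bag permutation."""

    response: str
    inc_mse: dict[str, float]  # percent increase in OOB MSE
    oob_mse: float
    settings: RFSettings

    def ranking(self) -> list[str]:
        """Predictors from most to least important."""
        return sorted(self.inc_mse, key=self.inc_mse.get, reverse=True)


def rf_importance(
    samples: pd.DataFrame,
    response: str = "vcmax25",
    predictors: tuple[str, ...] = (
        "n_area_ug_cm2",
        "chl_area_ug_cm2",
        "car_area_ug_cm2",
        "sla_cm2_g",
    ),
    settings: RFSettings = RFSettings(),
) -> ImportanceTable:
    """Random-forest permutation importance of leaf traits for a capacity.

    A bagged ensemble of regression trees (``n_trees`` bootstrap samples,
    ``max_features`` candidate predictors per split, default ⌈p/3⌉) is grown;
    for every tree the out-of-bag MSE is compared with the OOB MSE after
    permuting one predictor, and the percent increase is averaged over
    trees.  Fully deterministic given ``settings.seed``.
    """
    data = samples[[response, *predictors]].dropna()
    n = len(data)
    if n < settings.min_rows:
        raise ValueError(f"{n} complete rows < minimum {settings.min_rows}")
    x = data[list(predictors)].to_numpy(float)
    y = data[response].to_numpy(float)
    p = len(predictors)
    mf = settings.max_features or int(math.ceil(p / 3))
    root = np.random.default_rng(np.random.SeedSequence([settings.seed % (2**31), 7]))
    inc = np.zeros(p)
    n_used = 0
    oob_pred_sum = np.zeros(n)
    oob_pred_cnt = np.zeros(n)
    for _ in range(settings.n_trees):
        boot = root.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if len(oob) == 0:
            continue
        tree = DecisionTreeRegressor(
            max_features=mf, random_state=int(root.integers(0, 2**31 - 1))
        )
        tree.fit(x[boot], y[boot])
        pred = tree.predict(x[oob])
        mse0 = float(np.mean((pred - y[oob]) ** 2))
        oob_pred_sum[oob] += pred
        oob_pred_cnt[oob] += 1
        if mse0 == 0.0:
            continue
        for j in range(p):
            xp = x[oob].copy()
            xp[:, j] = xp[root.permutation(len(oob)), j]
            msep = float(np.mean((tree.predict(xp) - y[oob]) ** 2))
            inc[j] += 100.0 * (msep - mse0) / mse0
        n_used += 1
    if n_used == 0:
        raise RuntimeError("no tree produced out-of-bag samples")
    seen = oob_pred_cnt > 0
    oob_mse = float(np.mean((oob_pred_sum[seen] / oob_pred_cnt[seen] - y[seen]) ** 2))
    return ImportanceTable(
        response=response,
        inc_mse={pr: float(v / n_used) for pr, v in zip(predictors, inc)},
        oob_mse=oob_mse,
        settings=settings,
    )


@dataclass(frozen=True)
class TraitChange:
    """Change of one trait's per-DOY mean between two sampling days."""

    trait: str
    mean_from: float
    mean_to: float
    pct_rel_earlier: float  # 100*(to-from)/from
    pct_rel_later: float  # 100*(to-from)/to  (declines can exceed -100% only here)
    peak_doy: int
    peak_value: float


@dataclass
class SeasonalSummary:
    doy_from: int
    doy_to: int
    changes: dict[str, TraitChange]


def seasonal_changes(
    samples: pd.DataFrame,
    doy_from: int,
    doy_to: int,
    traits: list[str] | None = None,
) -> SeasonalSummary:
    """Percent change of per-DOY trait means between two sampling days.

    Both conventions are reported because neither is implied by phrases
    like "X% lower": relative to the earlier mean a decline is bounded at
    100%, relative to the later mean it is not.
    """
    if traits is None:
        traits = [c for c in samples.columns if samples[c].dtype.kind == "f"]
    by_doy = samples.groupby("doy")[traits].mean()
    for d in (doy_from, doy_to):
        if d not in by_doy.index:
            raise ValueError(f"DOY {d} not present in samples")
    changes = {}
    for t in traits:
        a, b = float(by_doy.loc[doy_from, t]), float(by_doy.loc[doy_to, t])
        peak_doy = int(by_doy[t].idxmax())
        changes[t] = TraitChange(
            trait=t,
            mean_from=a,
            mean_to=b,
            pct_rel_earlier=100.0 * (b - a) / a,
            pct_rel_later=100.0 * (b - a) / b,
            peak_doy=peak_doy,
            peak_value=float(by_doy[t].max()),
        )
    return SeasonalSummary(doy_from=doy_from, doy_to=doy_to, changes=changes)
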