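"""Regression layer: mixed-effects fits, type II (ranged major axis)
regression, climate residualization, and AIC all-subsets ranking.

The central object is :class:`MixedSlopeModel`, a scikit-learn style
estimator for a single-predictor linear mixed model with site as a random
grouping factor.  The random-effects structure (random intercept vs random
intercept + slope) is chosen by BIC on REML fits; the fixed-effect test is
a 1-df likelihood-ratio χ² between ML fits with and without the predictor
(a Wald χ² is available as an alternative).  :class:`RangedMajorAxis`
implements the type II regression used as a robustness check when both
axes carry sampling error.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "GroupingError",
    "DegenerateFitError",
    "PairingError",
    "CollinearityError",
    "MixedFitResult",
    "RmaResult",
    "MixedSlopeModel",
    "RangedMajorAxis",
    "fit_mixed",
    "rma_fit",
    "climate_residualize",
    "aic_all_subsets",
    "heterogeneity_interaction",
    "treatment_effects",
    "CLIMATE_COVARIATES",
]

CLIMATE_COVARIATES = ("MAT", "MAP", "temp_range", "temp_sd", "precip_cv", "temp_wettest4")


class GroupingError(ValueError):
    """Too few grouping levels for a random-effects fit."""


class DegenerateFitError(ValueError):
    """The response or predictor carries no usable variation."""


class PairingError(ValueError):
    """Pre/post block keys do not match."""


class CollinearityError(ValueError):
    """The fixed-effects design matrix is rank deficient."""


@dataclass
class MixedFitResult:
    """One fixed-effect slope from a linear mixed model."""

    slope: float
    intercept: float
    ci95: tuple[float, float]
    chi2: float
    p: float
    random_structure: str  # "intercept_only" | "intercept_and_slope"
    n_groups: int
    n_obs: int
    term: str = "predictor"
    notes: str = ""


@dataclass
class RmaResult:
    """Ranged-major-axis (type II) regression fit."""

    slope: float
    intercept: float
    ci95: tuple[float, float]
    n: int
    method: str = "ranged major axis"


def _fit_lmm(formula: str, df: pd.DataFrame, groups: str, re_formula=None, reml=False,
             thorough: bool = False):
    """MixedLM fit with optimizer fallbacks.

    Near-singular random-effects covariances can stall the default
    optimizer short of the optimum; retry with alternatives and keep the
    best-likelihood fit (preferring converged ones).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df[groups], re_formula=re_formula)
        best = None
        methods = (None, "powell", "cg") if thorough else (None, "powell")
        for method in methods:
            try:
                res = model.fit(reml=reml, maxiter=200, **({} if method is None else {"method": method}))
            except Exception:
                continue
            if not np.isfinite(res.llf):
                continue
            if best is None or res.llf > best.llf + 1e-10:
                best = res
            if not thorough and best.converged:
                break
        if best is None:
            raise DegenerateFitError(f"mixed model failed to fit: {formula}")
    return best


def _lrt(full_formula: str, red_formula: str, df: pd.DataFrame, groups: str, re_formula=None):
    """1-df ML likelihood-ratio test between nested mixed models.

    If the nesting inequality llf(full) >= llf(reduced) fails numerically,
    both models are refit with the extended optimizer sweep before the
    statistic is clipped at 0.
    """
    full = _fit_lmm(full_formula, df, groups, re_formula=re_formula, reml=False)
    red = _fit_lmm(red_formula, df, groups, re_formula=re_formula, reml=False)
    chi2 = 2.0 * (full.llf - red.llf)
    if chi2 < -1e-6:
        full = _fit_lmm(full_formula, df, groups, re_formula=re_formula, reml=False, thorough=True)
        red = _fit_lmm(red_formula, df, groups, re_formula=re_formula, reml=False, thorough=True)
        chi2 = 2.0 * (full.llf - red.llf)
    return full, max(0.0, float(chi2))


def _bic(res) -> float:
    # manual BIC so REML and ML fits are handled uniformly
    k = len(res.params)
    return float(-2.0 * res.llf + k * np.log(res.nobs))


class MixedSlopeModel(BaseEstimator):
    """Single-predictor linear mixed model with BIC-selected random structure.

    Parameters
    ----------
    select_random_slope : bool
        If True, compare {random intercept} vs {random intercept + random
        slope} by BIC on REML fits and keep the winner; singular or
        non-convergent random-slope fits fall back to intercept-only.
    test : {"lrt", "wald"}
        χ² test of the fixed effect: ML likelihood-ratio (default) or Wald.

    Attributes (after ``fit``)
    --------------------------
    slope_, intercept_, ci95_, chi2_, p_, random_structure_, n_groups_,
    n_obs_, result_ (a :class:`MixedFitResult`).
    """

    def __init__(self, select_random_slope: bool = True, test: str = "lrt"):
        self.select_random_slope = select_random_slope
        self.test = test

    def fit(self, X, y, groups):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        groups = np.asarray(groups)
        if not (len(x) == len(y) == len(groups)):
            raise ValueError("X, y and groups must have equal length")
        mask = np.isfinite(x) & np.isfinite(y)
        x, y, groups = x[mask], y[mask], groups[mask]
        if len(np.unique(groups)) < 2:
            raise GroupingError("mixed model requires >= 2 sites (grouping levels)")
        if len(y) < 3:
            raise DegenerateFitError("mixed model requires >= 3 observations")
        if np.std(y) == 0:
            raise DegenerateFitError("response has zero variance; fit is degenerate")
        if np.std(x) == 0:
            raise DegenerateFitError("predictor has zero variance; fit is degenerate")

        df = pd.DataFrame({"y": y, "x": x, "g": groups})

        # an (almost) exact linear relation leaves no residual variance for
        # the mixed model to estimate; report the deterministic fit directly
        b, a = np.polyfit(x, y, 1)
        resid_var = float(np.var(y - (a + b * x)))
        if resid_var < 1e-12 * float(np.var(y)):
            self.slope_ = float(b)
            self.intercept_ = float(a)
            self.ci95_ = (float(b), float(b))
            self.chi2_ = float("inf")
            self.p_ = 0.0
            self.random_structure_ = "intercept_only"
            self.n_groups_ = int(len(np.unique(groups)))
            self.n_obs_ = int(len(y))
            self.result_ = MixedFitResult(
                slope=self.slope_, intercept=self.intercept_, ci95=self.ci95_,
                chi2=self.chi2_, p=self.p_, random_structure=self.random_structure_,
                n_groups=self.n_groups_, n_obs=self.n_obs_,
                notes="response is an exact linear function of the predictor",
            )
            return self

        structure = "intercept_only"
        notes = ""
        if self.select_random_slope:
            try:
                r_int = _fit_lmm("y ~ x", df, "g", reml=True)
                r_slp = _fit_lmm("y ~ x", df, "g", re_formula="~x", reml=True)
                singular = (
                    not r_slp.converged
                    or np.min(np.linalg.eigvalsh(np.asarray(r_slp.cov_re))) < 1e-8
                )
                if not singular and _bic(r_slp) < _bic(r_int):
                    structure = "intercept_and_slope"
                elif singular:
                    notes = "random-slope fit singular; fell back to intercept-only"
            except Exception:
                notes = "random-slope fit failed; fell back to intercept-only"

        re_formula = "~x" if structure == "intercept_and_slope" else None
        if self.test == "wald":
            full = _fit_lmm("y ~ x", df, "g", re_formula=re_formula, reml=False)
            slope = float(full.fe_params["x"])
            se = float(full.bse_fe["x"])
            chi2 = (slope / se) ** 2 if se > 0 else np.inf
        elif self.test == "lrt":
            full, chi2 = _lrt("y ~ x", "y ~ 1", df, "g", re_formula=re_formula)
            slope = float(full.fe_params["x"])
            se = float(full.bse_fe["x"])
        else:
            raise ValueError(f"unknown test {self.test!r}")
        intercept = float(full.fe_params["Intercept"])
        ci = (slope - 1.959963984540054 * se, slope + 1.959963984540054 * se)
        p = float(stats.chi2.sf(chi2, df=1))

        self.slope_ = slope
        self.intercept_ = intercept
        self.ci95_ = ci
        self.chi2_ = float(chi2)
        self.p_ = p
        self.random_structure_ = structure
        self.n_groups_ = int(len(np.unique(groups)))
        self.n_obs_ = int(len(y))
        self.result_ = MixedFitResult(
            slope=slope,
            intercept=intercept,
            ci95=ci,
            chi2=float(chi2),
            p=p,
            random_structure=structure,
            n_groups=self.n_groups_,
            n_obs=self.n_obs_,
            notes=notes,
        )
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.slope_ * x


def fit_mixed(response, predictor, site, test: str = "lrt") -> MixedFitResult:
    """Fit response ~ predictor with site random effects; see MixedSlopeModel."""
    return MixedSlopeModel(test=test).fit(predictor, response, site).result_


class RangedMajorAxis(BaseEstimator):
    """Type II regression by the ranged major axis method.

    Both variables are scaled by their ranges, the major-axis slope is the
    leading eigenvector of the 2x2 covariance matrix of the ranged
    variables, and the slope is back-transformed by the range ratio.  The
    intercept passes through the means.  The 95% CI uses the closed-form
    confidence limits for the major-axis angle,
    θ ± ½·arcsin(2√H) with H = F(1, n−2)·λ₁λ₂ / ((n−2)(λ₁−λ₂)²),
    computed on the ranged variables and back-transformed.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        mask = np.isfinite(x) & np.isfinite(y)
        x, y = x[mask], y[mask]
        n = len(x)
        if n < 3:
            raise DegenerateFitError("RMA requires >= 3 points")
        rx = float(np.ptp(x))
        ry = float(np.ptp(y))
        if rx == 0 or ry == 0:
            raise DegenerateFitError("RMA requires nonzero range in both variables")
        xr, yr = x / rx, y / ry
        cov = np.cov(xr, yr)
        eigval, eigvec = np.linalg.eigh(cov)
        # eigh sorts ascending: the major axis is the last eigenvector
        v = eigvec[:, -1]
        if v[0] == 0:
            raise DegenerateFitError("major axis is vertical; slope undefined")
        b_ranged = v[1] / v[0]
        # orient the axis along the sign of the covariance
        if cov[0, 1] != 0 and np.sign(b_ranged) != np.sign(cov[0, 1]):
            b_ranged = -b_ranged
        l1, l2 = eigval[-1], eigval[0]
        theta = np.arctan(b_ranged)
        if l1 > l2 and n > 2:
            f = stats.f.ppf(1 - self.alpha, 1, n - 2)
            h = f * l1 * l2 / ((n - 2) * (l1 - l2) ** 2)
            if 2 * np.sqrt(max(h, 0.0)) < 1:
                half = 0.5 * np.arcsin(2 * np.sqrt(max(h, 0.0)))
                lo, hi = np.tan(theta - half), np.tan(theta + half)
            else:
                lo, hi = -np.inf, np.inf
        else:
            lo, hi = -np.inf, np.inf
        scale = ry / rx
        slope = float(b_ranged * scale)
        self.slope_ = slope
        self.intercept_ = float(y.mean() - slope * x.mean())
        self.ci95_ = (float(lo * scale), float(hi * scale))
        self.n_ = n
        self.result_ = RmaResult(self.slope_, self.intercept_, self.ci95_, n)
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.slope_ * x


def rma_fit(x, y, alpha: float = 0.05) -> RmaResult:
    """Ranged-major-axis type II regression of y on x."""
    return RangedMajorAxis(alpha=alpha).fit(x, y).result_


def climate_residualize(
    response: pd.Series, climate: pd.DataFrame, covariates: Sequence[str] = CLIMATE_COVARIATES
) -> pd.Series:
    """Residuals of an OLS multiple regression of response on climate.

    ``response`` and ``climate`` must be aligned (e.g. both indexed by
    site).  Covariates that are constant are dropped with a warning; exact
    collinearity among the remaining columns raises
    :class:`CollinearityError` naming the aliased columns.
    """
    cols = [c for c in covariates if c in climate.columns]
    if not cols:
        raise ValueError(f"none of the climate covariates {list(covariates)} present")
    y = pd.to_numeric(response)
    x = climate[cols].apply(pd.to_numeric)
    usable = []
    for c in cols:
        if x[c].std(ddof=0) == 0:
            warnings.warn(f"climate covariate {c!r} is constant; dropped")
        else:
            usable.append(c)
    if not usable:
        return y - y.mean()
    xm = x[usable].to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(xm)), xm])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        aliased = []
        base = np.ones((len(xm), 1))
        for i, c in enumerate(usable):
            cand = np.column_stack([base, xm[:, i]])
            if np.linalg.matrix_rank(cand) == base.shape[1]:
                aliased.append(c)
            else:
                base = cand
        raise CollinearityError(f"climate design is rank deficient; aliased columns: {aliased}")
    if len(y) <= len(usable) + 1:
        raise ValueError("need more observations than covariates + 1")
    res = sm.OLS(y.to_numpy(dtype=float), design).fit()
    return pd.Series(res.resid, index=response.index, name="residual")


def aic_all_subsets(
    response,
    predictors: pd.DataFrame,
    interactions: Sequence[tuple[str, str]] = (),
    use_aicc: bool = False,
) -> pd.DataFrame:
    """Exhaustive OLS all-subsets ranking by AIC.

    Candidate terms are the predictor columns plus the requested pairwise
    interactions; an interaction enters a model only when both of its main
    effects do.  Returns one row per candidate model with terms, k, AIC,
    ΔAIC and Akaike weights, best first.
    """
    y = np.asarray(response, dtype=float)
    mains = list(predictors.columns)
    inter = [tuple(t) for t in interactions]
    for a, b in inter:
        if a not in mains or b not in mains:
            raise ValueError(f"interaction ({a}, {b}) references unknown main effects")
    n_terms = len(mains) + len(inter)
    if n_terms > 12:
        raise ValueError(
            f"{n_terms} candidate terms exceed the exhaustive-enumeration limit of 12; "
            "prune the candidate set or fit a single specified model instead"
        )
    xcols = {c: predictors[c].to_numpy(dtype=float) for c in mains}
    rows = []
    for r in range(len(mains) + 1):
        for subset in itertools.combinations(mains, r):
            admissible = [t for t in inter if t[0] in subset and t[1] in subset]
            for ri in range(len(admissible) + 1):
                for isub in itertools.combinations(admissible, ri):
                    cols = [xcols[c] for c in subset]
                    cols += [xcols[a] * xcols[b] for a, b in isub]
                    design = np.column_stack([np.ones(len(y))] + cols)
                    fit = sm.OLS(y, design).fit()
                    k = design.shape[1] + 1  # + residual variance
                    aic = float(fit.aic)
                    if use_aicc:
                        denom = len(y) - k - 1
                        aic = aic + (2 * k * (k + 1) / denom if denom > 0 else np.inf)
                    terms = list(subset) + [f"{a}:{b}" for a, b in isub]
                    rows.append({"terms": "+".join(terms) or "1", "k": k, "aic": aic})
    table = pd.DataFrame(rows).sort_values("aic", kind="mergesort").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    w = np.exp(-0.5 * table["delta_aic"])
    table["weight"] = w / w.sum()
    return table


def _stack_phases(
    metrics_pre: pd.DataFrame, metrics_post: pd.DataFrame, columns: Sequence[str]
) -> pd.DataFrame:
    keys_pre = set(map(tuple, metrics_pre[["site_id", "block_id"]].values))
    keys_post = set(map(tuple, metrics_post[["site_id", "block_id"]].values))
    if keys_pre != keys_post:
        offenders = sorted(keys_pre.symmetric_difference(keys_post))
        raise PairingError(f"unmatched site/block keys across phases: {offenders[:10]}")
    cols = ["site_id", "block_id", *columns]
    pre = metrics_pre[cols].copy()
    pre["phase"] = 0
    post = metrics_post[cols].copy()
    post["phase"] = 1
    return pd.concat([pre, post], ignore_index=True)


def heterogeneity_interaction(
    metrics_pre: pd.DataFrame,
    metrics_post: pd.DataFrame,
    predictor: str,
    response: str = "log_cv",
) -> MixedFitResult:
    """Diversity x heterogeneity-phase interaction on spatial variability.

    Stacks matched pre/post block metrics with a phase factor (0 = ambient,
    1 = enhanced heterogeneity) and fits ``response ~ predictor * phase``
    with a site random intercept.  The returned slope is the interaction
    coefficient; χ² is the 1-df ML likelihood-ratio test of that term.
    """
    df = _stack_phases(metrics_pre, metrics_post, [predictor, response])
    df = df.rename(columns={predictor: "x", response: "y"})
    df = df[np.isfinite(df["x"]) & np.isfinite(df["y"])]
    if df["site_id"].nunique() < 2:
        raise GroupingError("interaction model requires >= 2 sites")
    full, chi2 = _lrt("y ~ x * phase", "y ~ x + phase", df, "site_id")
    slope = float(full.fe_params["x:phase"])
    se = float(full.bse_fe["x:phase"])
    return MixedFitResult(
        slope=slope,
        intercept=float(full.fe_params["Intercept"]),
        ci95=(slope - 1.959963984540054 * se, slope + 1.959963984540054 * se),
        chi2=float(chi2),
        p=float(stats.chi2.sf(chi2, df=1)),
        random_structure="intercept_only",
        n_groups=int(df["site_id"].nunique()),
        n_obs=int(len(df)),
        term=f"{predictor}:phase",
    )


def treatment_effects(
    metrics_pre: pd.DataFrame, metrics_post: pd.DataFrame, metric: str
) -> MixedFitResult:
    """Phase main effect (enhanced heterogeneity vs ambient) on one metric."""
    df = _stack_phases(metrics_pre, metrics_post, [metric])
    df = df.rename(columns={metric: "y"})
    df = df[np.isfinite(df["y"])]
    if df["site_id"].nunique() < 2:
        raise GroupingError("treatment-effect model requires >= 2 sites")
    if df["y"].std() == 0:
        # identical phases: the effect is exactly 0 and the LRT is vacuous
        return MixedFitResult(
            slope=0.0,
            intercept=float(df["y"].mean()),
            ci95=(0.0, 0.0),
            chi2=0.0,
            p=1.0,
            random_structure="intercept_only",
            n_groups=int(df["site_id"].nunique()),
            n_obs=int(len(df)),
            term=f"phase->{metric}",
            notes="response constant across phases",
        )
    full, chi2 = _lrt("y ~ phase", "y ~ 1", df, "site_id")
    slope = float(full.fe_params["phase"])
    se = float(full.bse_fe["phase"])
    return MixedFitResult(
        slope=slope,
        intercept=float(full.fe_params["Intercept"]),
        ci95=(slope - 1.959963984540054 * se, slope + 1.959963984540054 * se),
        chi2=float(chi2),
        p=float(stats.chi2.sf(chi2, df=1)),
        random_structure="intercept_only",
        n_groups=int(df["site_id"].nunique()),
        n_obs=int(len(df)),
        term=f"phase->{metric}",
    )
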