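"""Complementary log-log linear regression with backward-forward AIC selection.

The response, a concentration bounded in ``(0, cd_max)``, is mapped onto the
real line by

    z = ln(ln(cd_max / y)),

the inverse of the Gumbel CDF applied to ``y / cd_max``.  A Gaussian linear
model is then fitted to ``z`` by ordinary least squares:

    z_i = alpha + sum_j beta_j x_i^j + eps_i,   eps_i ~ N(0, sigma^2).

Back-transforming a fitted linear predictor through
``y = cd_max * exp(-exp(eta))`` gives the *median* of the concentration
given eta (the transform is monotone), always inside ``(0, cd_max)``.

Model selection is best-first backward-forward stepwise on the AIC
``-2 loglik + 2 (k_params + 1)`` — the +1 counts the variance parameter.
Categorical variables (species, tree cover, zone) move as whole dummy
blocks, mirroring selection on *variables* rather than individual columns.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import REFERENCE_LEVELS
from .synthetic import SiteTable, RESPONSE

CATEGORICAL_VARS = tuple(REFERENCE_LEVELS)


class RankDeficientError(ValueError):
    """Raised when the design matrix has linearly dependent columns."""

    def __init__(self, aliased):
        self.aliased = list(aliased)
        super().__init__(
            "rank-deficient design; aliased columns: " + ", ".join(self.aliased))


class DomainError(ValueError):
    pass


# -- transform -------------------------------------------------------------

def cll_transform(y, cd_max: float):
    """z = ln(ln(cd_max / y)); strictly decreasing in y on (0, cd_max)."""
    y_arr = np.asarray(y, float)
    bad = ~((y_arr > 0) & (y_arr < cd_max))
    if np.any(bad):
        idx = np.flatnonzero(np.atleast_1d(bad))
        raise DomainError(
            f"response outside (0, {cd_max}) at positions {idx.tolist()[:10]}: "
            f"values {np.atleast_1d(y_arr)[idx][:10].tolist()}")
    return np.log(np.log(cd_max / y_arr))


def inverse_cll(eta, cd_max: float):
    """y = cd_max * exp(-exp(eta)), mapping any real eta into (0, cd_max).

    Extreme linear predictors are clipped to the nearest representable
    value strictly inside the open interval, so the bound invariant holds
    even where ``exp`` under- or overflows in floating point.
    """
    with np.errstate(over="ignore"):
        y = cd_max * np.exp(-np.exp(np.asarray(eta, float)))
    return np.clip(y, np.nextafter(0.0, 1.0), np.nextafter(cd_max, 0.0))


# -- design matrix ---------------------------------------------------------

@dataclass
class DesignInfo:
    """Dummy-coding recipe: per categorical variable, the reference level
    and the ordered non-reference levels observed in the training data."""

    categorical: dict  # name -> (reference, [levels coded as dummies])

    def columns_for(self, var: str) -> list:
        if var in self.categorical:
            ref, levels = self.categorical[var]
            return [f"{var}[{lv}]" for lv in levels]
        return [var]


def build_design_info(df: pd.DataFrame, variables) -> DesignInfo:
    cat = {}
    for var in variables:
        if var in CATEGORICAL_VARS:
            ref = REFERENCE_LEVELS[var]
            levels = sorted(lv for lv in df[var].unique() if lv != ref)
            cat[var] = (ref, levels)
    return DesignInfo(cat)


def design_matrix(df: pd.DataFrame, variables, info: DesignInfo,
                  strict_levels: bool = True):
    """Intercept + covariates + dummy blocks, in a fixed column order.

    With ``strict_levels=False`` unseen categorical levels are coded as the
    reference (all dummies zero) and the affected row indices are returned
    in the second element.
    """
    cols = {"Intercept": np.ones(len(df))}
    flagged = np.zeros(len(df), bool)
    for var in variables:
        if var in info.categorical:
            ref, levels = info.categorical[var]
            known = set(levels) | {ref}
            unseen = ~df[var].isin(known).to_numpy()
            if unseen.any():
                if strict_levels:
                    bad = sorted(df[var][unseen].unique())
                    raise ValueError(f"unseen level(s) {bad} for {var!r}")
                flagged |= unseen
            for lv in levels:
                cols[f"{var}[{lv}]"] = (df[var] == lv).to_numpy(float)
        else:
            if var not in df.columns:
                raise KeyError(f"variable {var!r} missing from table")
            cols[var] = df[var].to_numpy(float)
    X = pd.DataFrame(cols, index=df.index)
    return X, np.flatnonzero(flagged)


def _aliased_columns(X: pd.DataFrame) -> list:
    """Columns involved in linear dependencies, via the SVD null space."""
    arr = X.to_numpy(float)
    _, s, vt = np.linalg.svd(arr, full_matrices=False)
    tol = s.max() * max(arr.shape) * np.finfo(float).eps
    null = vt[s < tol] if np.any(s < tol) else vt[len(s):]
    involved = np.any(np.abs(null) > 1e-8, axis=0)
    return [c for c, flag in zip(X.columns, involved) if flag]


# -- fit -------------------------------------------------------------------

@dataclass
class CLLFit:
    cd_max: float
    alpha: float
    betas: dict
    sigma2_hat: float            # ML estimate RSS / M
    coef_cov: pd.DataFrame       # unbiased-sigma^2 scaling
    n_obs: int
    k_params: int                # mean parameters incl. intercept
    loglik: float
    aic: float
    p_values: pd.Series
    design_info: DesignInfo
    variables: list
    params: pd.Series = field(repr=False, default=None)
    std_errors: pd.Series = field(repr=False, default=None)

    def coefficient_table(self) -> pd.DataFrame:
        """Term/estimate/SE/t/p table with significance stars."""
        t = self.params / self.std_errors
        stars = pd.cut(self.p_values, [-np.inf, 0.001, 0.01, 0.05, np.inf],
                       labels=["***", "**", "*", ""]).astype(str)
        return pd.DataFrame({
            "term": self.params.index,
            "estimate": self.params.values,
            "std_error": self.std_errors.values,
            "t_value": t.values,
            "p_value": self.p_values.values,
            "signif": stars.values,
        })


def fit_cll(sites: SiteTable, variables, cd_max: float = None,
            response_col: str = RESPONSE) -> CLLFit:
    """OLS fit of the transformed response on the given variables.

    Categorical design variables are dummy-coded against the fixed
    reference levels (Hc moss, deciduous cover, Alpine zone).  Raises
    :class:`RankDeficientError` listing aliased columns when the design is
    singular, and an error when there are no residual degrees of freedom.
    """
    cd_max = sites.cd_max if cd_max is None else cd_max
    variables = list(variables)
    z = cll_transform(sites.data[response_col].to_numpy(), cd_max)
    info = build_design_info(sites.data, variables)
    X, _ = design_matrix(sites.data, variables, info)
    M, k = X.shape
    if M <= k:
        raise ValueError(f"{M} observations cannot identify {k} mean parameters")
    if np.linalg.matrix_rank(X.to_numpy()) < k:
        raise RankDeficientError(_aliased_columns(X))
    res = sm.OLS(z, X).fit()
    rss = float(res.ssr)
    sigma2_ml = rss / M
    loglik = -0.5 * M * (np.log(2.0 * np.pi * max(sigma2_ml, 1e-300)) + 1.0)
    aic = -2.0 * loglik + 2.0 * (k + 1)
    params = pd.Series(res.params, index=X.columns)
    se = pd.Series(res.bse, index=X.columns)
    pvals = pd.Series(res.pvalues, index=X.columns)
    if sigma2_ml == 0.0:
        # exact interpolation: SEs collapse, p-values undefined
        pvals = pd.Series(np.where(params.abs() > 0, 0.0, 1.0), index=X.columns)
    cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    return CLLFit(
        cd_max=cd_max,
        alpha=float(params["Intercept"]),
        betas={c: float(v) for c, v in params.items() if c != "Intercept"},
        sigma2_hat=sigma2_ml,
        coef_cov=cov,
        n_obs=M,
        k_params=k,
        loglik=float(loglik),
        aic=float(aic),
        p_values=pvals,
        design_info=info,
        variables=variables,
        params=params,
        std_errors=se,
    )


# -- stepwise AIC ----------------------------------------------------------

@dataclass
class SelectionTrace:
    steps: list = field(default_factory=list)  # (action, variable, aic_before, aic_after)
    final_variables: list = field(default_factory=list)
    final_aic: float = np.nan
    skipped: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps,
                            columns=["action", "variable", "aic_before", "aic_after"])


def _try_fit(sites, variables, cd_max, response_col, skipped, tag):
    try:
        return fit_cll(sites, variables, cd_max, response_col)
    except (RankDeficientError, ValueError) as exc:
        skipped.append((tag, str(exc)))
        return None


def stepwise_aic(sites: SiteTable, start_variables, cd_max: float = None,
                 response_col: str = RESPONSE,
                 candidate_variables=None) -> tuple:
    """Best-first backward-forward selection minimising AIC.

    At each iteration every single-variable drop from the current model and
    every add from the excluded pool is scored, and the move with the
    largest AIC decrease is applied; iteration stops when no move lowers
    the AIC.  Candidate fits that are rank-deficient (or lack residual
    degrees of freedom) are skipped and logged.  If the full starting model
    itself is not estimable — typical when a small zone has nearly as many
    screened covariates as observations — selection starts from the
    intercept-only model instead, with the same move rules.
    """
    cd_max = sites.cd_max if cd_max is None else cd_max
    start_variables = list(start_variables)
    pool = list(candidate_variables) if candidate_variables is not None \
        else list(start_variables)
    trace = SelectionTrace()

    current = list(start_variables)
    fit = _try_fit(sites, current, cd_max, response_col, trace.skipped, "start:full")
    if fit is None:
        current = []
        fit = fit_cll(sites, current, cd_max, response_col)

    while True:
        moves = []
        for var in current:
            cand = [v for v in current if v != var]
            f = _try_fit(sites, cand, cd_max, response_col,
                         trace.skipped, f"drop:{var}")
            if f is not None:
                moves.append(("drop", var, f))
        for var in pool:
            if var in current:
                continue
            f = _try_fit(sites, current + [var], cd_max, response_col,
                         trace.skipped, f"add:{var}")
            if f is not None:
                moves.append(("add", var, f))
        if not moves:
            break
        action, var, best = min(moves, key=lambda m: (m[2].aic, m[1]))
        if best.aic < fit.aic - 1e-10:
            trace.steps.append((action, var, fit.aic, best.aic))
            fit = best
            current = list(best.variables)
        else:
            break

    trace.final_variables = list(current)
    trace.final_aic = fit.aic
    return fit, trace
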