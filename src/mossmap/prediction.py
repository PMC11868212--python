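"""Grid extrapolation of a fitted CLL model with delta-method uncertainty.

For each grid cell s the linear predictor eta_hat(s) = x(s)' b is evaluated
with the categorical design fixed at a reference profile (by default Hc
moss under deciduous cover, so the map shows what that species would
accumulate at every location).  The concentration prediction is the median
back-transform

    y_hat(s) = cd_max * exp(-exp(eta_hat(s)))

— the median of Y given eta because the transform is monotone — and its
standard deviation follows from the delta method,

    sd_y(s) = |d y / d eta| * se_eta(s),
    d y / d eta = -cd_max * exp(eta - exp(eta)),

where se_eta is the standard error of the fitted mean from the coefficient
covariance.  A flag can add the residual variance for a prediction-scale
SD instead.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .cll import CLLFit, design_matrix, inverse_cll

DEFAULT_PROFILE = {"moss_species": "Hc", "tree_cover": "deciduous"}


def delta_sd(eta, se_eta, cd_max: float):
    """|dy/deta| * se_eta with dy/deta = -cd_max * exp(eta - exp(eta))."""
    eta = np.asarray(eta, float)
    return cd_max * np.exp(eta - np.exp(eta)) * np.asarray(se_eta, float)


def predict_grid(fit: CLLFit, grid: pd.DataFrame, profile: dict = None,
                 include_residual_var: bool = False,
                 training_ranges: pd.DataFrame = None) -> pd.DataFrame:
    """Predict over a covariate grid.

    ``profile`` supplies levels for categoricals in the model that are not
    columns of the grid (grid columns such as ``zone`` take precedence).
    Cells missing any selected covariate are excluded from the output and
    counted in ``attrs["n_missing"]``.  If ``training_ranges`` (a frame
    with ``min``/``max`` rows per covariate, e.g. from
    :func:`covariate_ranges`) is given, cells with any covariate outside
    the observed range are flagged ``extrapolated`` rather than masked.
    """
    profile = {**DEFAULT_PROFILE, **(profile or {})}
    work = grid.copy()
    for var in fit.variables:
        if var in fit.design_info.categorical and var not in work.columns:
            if var not in profile:
                raise ValueError(f"profile must supply a level for {var!r}")
            work[var] = profile[var]
        elif var in fit.design_info.categorical and var in profile:
            work[var] = profile[var]

    quantitative = [v for v in fit.variables
                    if v not in fit.design_info.categorical]
    missing_cols = [v for v in quantitative if v not in work.columns]
    if missing_cols:
        raise KeyError(f"grid lacks covariate column(s) {missing_cols}")
    ok_rows = ~work[quantitative].isna().any(axis=1) if quantitative \
        else pd.Series(True, index=work.index)
    n_missing = int((~ok_rows).sum())
    work = work[ok_rows]

    X, _ = design_matrix(work, fit.variables, fit.design_info)
    X = X[fit.params.index]  # column order of the fit
    eta = X.to_numpy() @ fit.params.to_numpy()
    cov = fit.coef_cov.to_numpy()
    var_eta = np.einsum("ij,jk,ik->i", X.to_numpy(), cov, X.to_numpy())
    if include_residual_var:
        # unbiased residual variance, consistent with the coefficient SEs
        dof = fit.n_obs - fit.k_params
        var_eta = var_eta + fit.sigma2_hat * fit.n_obs / max(dof, 1)
    se_eta = np.sqrt(np.maximum(var_eta, 0.0))

    out = work[[c for c in ("cell_id", "x", "y", "zone") if c in work.columns]].copy()
    out["eta_hat"] = eta
    out["se_eta"] = se_eta
    out["y_hat"] = inverse_cll(eta, fit.cd_max)
    out["sd_y"] = delta_sd(eta, se_eta, fit.cd_max)
    for key, val in profile.items():
        out[f"profile_{key}"] = val

    if training_ranges is not None:
        extrap = np.zeros(len(out), bool)
        for v in quantitative:
            if v in training_ranges.columns:
                lo, hi = training_ranges.loc["min", v], training_ranges.loc["max", v]
                extrap |= (work[v].to_numpy() < lo) | (work[v].to_numpy() > hi)
        out["extrapolated"] = extrap
    out.attrs["n_missing"] = n_missing
    out.attrs["n_cells"] = len(out)
    return out.reset_index(drop=True)


def covariate_ranges(sites_df: pd.DataFrame, variables) -> pd.DataFrame:
    quant = [v for v in variables if v in sites_df.columns
             and pd.api.types.is_numeric_dtype(sites_df[v])]
    return pd.DataFrame({v: [sites_df[v].min(), sites_df[v].max()]
                         for v in quant}, index=["min", "max"])


def mosaic_zone_maps(per_zone_predictions) -> pd.DataFrame:
    """Merge per-zone prediction frames into one national map.

    Each cell must be claimed by exactly one zone map; duplicate or
    conflicting claims raise.  The output records zone borders implicitly
    through the ``zone`` column (rendered as white lines on maps).
    """
    frames = list(per_zone_predictions)
    if not frames:
        raise ValueError("no zone maps to mosaic")
    merged = pd.concat(frames, ignore_index=True)
    key = "cell_id" if "cell_id" in merged.columns else None
    dup = merged.duplicated(subset=[key] if key else ["x", "y"])
    if dup.any():
        raise ValueError(f"{int(dup.sum())} grid cell(s) claimed by more than one zone")
    order = ["y", "x"] if key is None else [key]
    return merged.sort_values(order).reset_index(drop=True)
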