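"""Ordinary kriging of log-transformed concentrations: the covariate-free
baseline map.

The empirical semivariogram of ``log(Y)`` is estimated with the classical
(Matheron) estimator, a parametric model (exponential by default) is fitted
by weighted least squares with pair counts as weights, and predictions are
obtained by solving the ordinary-kriging system — weights constrained to
sum to one through a Lagrange multiplier — at every grid cell.  Point
predictions are back-transformed by exponentiation (no lognormal bias
correction; the resulting median-type map mirrors the regression map's
semantics) and the kriging standard deviation is carried to the
concentration scale with the delta method, ``sd_y = y_hat * sd_log``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist, pdist, squareform

from .synthetic import SiteTable, RESPONSE

FAMILIES = ("exponential", "spherical", "gaussian")


def semivariance(family: str, h, nugget: float, partial_sill: float,
                 range_: float):
    """gamma(h); gamma(0) = nugget by construction (models are continuous
    from the right, the nugget acts only for h > 0 in the kriging matrix
    through the conventional zero diagonal)."""
    h = np.asarray(h, float)
    if family == "exponential":
        struct = 1.0 - np.exp(-3.0 * h / range_)
    elif family == "gaussian":
        struct = 1.0 - np.exp(-3.0 * (h / range_) ** 2)
    elif family == "spherical":
        hr = np.minimum(h / range_, 1.0)
        struct = 1.5 * hr - 0.5 * hr ** 3
    else:
        raise ValueError(f"unknown variogram family {family!r}")
    return nugget + partial_sill * struct


@dataclass
class VariogramModel:
    family: str
    nugget: float
    partial_sill: float
    range_: float
    objective: float = np.nan
    empirical_bins: pd.DataFrame = None  # lag, gamma, n_pairs

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.nugget < 0 or self.partial_sill < 0 or self.range_ <= 0:
            raise ValueError("invalid variogram parameters")

    def __call__(self, h):
        return semivariance(self.family, h, self.nugget, self.partial_sill,
                            self.range_)

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill


def empirical_variogram(coords: np.ndarray, values: np.ndarray,
                        n_bins: int = 15, max_lag: float = None,
                        edges: np.ndarray = None) -> pd.DataFrame:
    """Matheron estimator: gamma(h) = mean of squared increments / 2 within
    distance bins up to ``max_lag`` (default: half the maximum distance).

    The reported lag of each bin is the mean pair distance within it,
    which keeps short-lag bins honest when the design includes close
    pairs.  ``edges`` overrides the default equal-width binning.
    """
    d = pdist(coords)
    if np.ptp(d) == 0:
        raise ValueError("all pairwise distances identical")
    if edges is None:
        if max_lag is None:
            max_lag = 0.5 * d.max()
        edges = np.linspace(0.0, max_lag, n_bins + 1)
    sq = 0.5 * pdist(values.reshape(-1, 1), metric="sqeuclidean")
    which = np.digitize(d, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        mask = which == b
        if mask.sum() == 0:
            continue
        rows.append((float(d[mask].mean()),
                     float(sq[mask].mean()), int(mask.sum())))
    return pd.DataFrame(rows, columns=["lag", "gamma", "n_pairs"])


def fit_variogram(obs: SiteTable, family: str = "exponential",
                  n_bins: int = 15, max_lag: float = None,
                  response_col: str = RESPONSE,
                  log_transform: bool = True) -> VariogramModel:
    """Fit a variogram to (log-transformed) observations by WLS with pair
    counts as weights."""
    if obs.n < 10:
        raise ValueError("need at least 10 sites to fit a variogram")
    values = obs.data[response_col].to_numpy(float)
    if log_transform:
        values = np.log(values)
    return fit_variogram_xy(obs.coords(), values, family, n_bins, max_lag)


def fit_variogram_xy(coords, values, family: str = "exponential",
                     n_bins: int = 15, max_lag: float = None,
                     edges: np.ndarray = None) -> VariogramModel:
    coords = np.asarray(coords, float)
    values = np.asarray(values, float)
    bins = empirical_variogram(coords, values, n_bins, max_lag, edges)
    lags = bins["lag"].to_numpy()
    gammas = bins["gamma"].to_numpy()
    weights = np.sqrt(bins["n_pairs"].to_numpy(float))

    var_total = max(values.var(), 1e-12)
    x0 = np.array([0.5 * gammas[0], max(var_total - 0.5 * gammas[0], 1e-6),
                   max(lags.max() / 3.0, lags[0])])
    lb = np.array([0.0, 0.0, lags[0] * 1e-3])
    ub = np.array([np.inf, np.inf, 10.0 * lags.max()])

    def resid(p):
        return weights * (semivariance(family, lags, *p) - gammas)

    sol = least_squares(resid, np.clip(x0, lb + 1e-12, ub), bounds=(lb, ub))
    nugget, psill, rng_ = sol.x
    return VariogramModel(family, float(nugget), float(psill), float(rng_),
                          objective=float(2.0 * sol.cost),
                          empirical_bins=bins)


def _ok_system(coords: np.ndarray, vgm: VariogramModel):
    n = len(coords)
    gamma = vgm(squareform(pdist(coords)))
    np.fill_diagonal(gamma, 0.0)
    a = np.zeros((n + 1, n + 1))
    a[:n, :n] = gamma
    a[n, :n] = 1.0
    a[:n, n] = 1.0
    return a


def _solve_ok(coords, values, vgm, targets):
    """Kriging weights, predictions and variances for target points."""
    n = len(coords)
    a = _ok_system(coords, vgm)

    def factor(mat):
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            lu_ = lu_factor(mat)
        piv = np.abs(np.diag(lu_[0]))
        scale = max(piv.max(), 1.0)
        if not np.all(np.isfinite(lu_[0])) or piv.min() < 1e-12 * scale:
            return None
        return lu_

    lu = factor(a)
    if lu is None:
        # jitter-and-retry once (duplicate sites / zero nugget)
        jitter = 1e-8 * max(float(np.abs(a).max()), 1.0)
        a2 = a.copy()
        a2[:n, :n] += np.eye(n) * jitter
        lu = factor(a2)
        if lu is None:
            raise np.linalg.LinAlgError("singular ordinary-kriging system")
    g0 = vgm(cdist(targets, coords))  # (m, n)
    rhs = np.concatenate([g0, np.ones((len(targets), 1))], axis=1).T
    sol = lu_solve(lu, rhs)  # (n+1, m)
    lam = sol[:n].T
    mu = sol[n]
    pred = lam @ values
    var = np.einsum("mn,mn->m", lam, g0) + mu
    return lam, pred, np.maximum(var, 0.0)


def ok_predict(obs: SiteTable, vgm: VariogramModel, grid: pd.DataFrame,
               response_col: str = RESPONSE, log_transform: bool = True,
               max_neighbors: int = 64) -> pd.DataFrame:
    """Ordinary-kriging predictions over a grid.

    Uses the global neighbourhood (all sites in every system) up to 500
    sites, otherwise the nearest ``max_neighbors`` sites per cell.  Returns
    a frame with log-scale prediction and SD plus back-transformed
    ``y_hat`` and delta-method ``sd_y``; OK weights sum to one at every
    cell by construction of the constrained system.
    """
    coords = obs.coords()
    values = obs.data[response_col].to_numpy(float)
    if log_transform:
        values = np.log(values)
    targets = grid[["x", "y"]].to_numpy(float)
    if len(coords) <= 500:
        lam, pred, var = _solve_ok(coords, values, vgm, targets)
        wsum = lam.sum(axis=1)
    else:
        from scipy.spatial import cKDTree
        tree = cKDTree(coords)
        _, nn = tree.query(targets, k=max_neighbors)
        pred = np.empty(len(targets))
        var = np.empty(len(targets))
        wsum = np.empty(len(targets))
        for i, idx in enumerate(nn):
            lam_i, p_i, v_i = _solve_ok(coords[idx], values[idx], vgm,
                                        targets[i:i + 1])
            pred[i], var[i], wsum[i] = p_i[0], v_i[0], lam_i.sum()
    sd_log = np.sqrt(var)
    out = grid[[c for c in ("cell_id", "x", "y", "zone") if c in grid.columns]].copy()
    out["pred_log"] = pred
    out["sd_log"] = sd_log
    if log_transform:
        out["y_hat"] = np.exp(pred)
        out["sd_y"] = out["y_hat"] * sd_log  # delta method
    else:
        out["y_hat"] = pred
        out["sd_y"] = sd_log
    out["weight_sum"] = wsum
    return out
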