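"""Synthetic site tables, prediction grids and CLL-model responses.

The generator emulates the design of a national moss-biomonitoring
campaign: sites in rectangular biogeographical zones, categorical moss
species / tree cover drawn with fixed frequencies, quantitative covariates
produced from shared latent Gaussian fields (so buffer families are
strongly rank-correlated and grids are coherent with sites), and a bounded
response drawn from the complementary log-log model

    ln(ln(cd_max / Y_i)) = alpha + sum_j beta_j X_i^j + eps_i,
    eps_i ~ N(0, sigma^2),

whose inverse maps every real linear predictor into (0, cd_max).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import StudyConfig, CovariateSpec
from .fields import LatentField, CorrelatedFamily

RESPONSE = "cd"
ID_COLS = ("site_id", "x", "y", "zone", "moss_species", "tree_cover")


@dataclass
class SiteTable:
    """Observation table plus minimal metadata.

    ``data`` holds one row per site with identifier, planar coordinates in
    metres, categorical design columns, the quantitative covariates and —
    after :func:`simulate_response` — the concentration column ``cd``.
    """

    data: pd.DataFrame
    covariates: list
    cd_max: float = 1.5
    meta: dict = dc_field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def has_response(self) -> bool:
        return RESPONSE in self.data.columns

    def subset(self, zone: str) -> "SiteTable":
        sub = self.data[self.data["zone"] == zone].reset_index(drop=True)
        return SiteTable(sub, list(self.covariates), self.cd_max,
                         {**self.meta, "scope": zone})

    def coords(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy(float)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, covariates=None,
                   cd_max: float = 1.5, meta=None) -> "SiteTable":
        """Wrap an externally built table; covariates default to every
        numeric column that is not an identifier or the response."""
        if covariates is None:
            skip = set(ID_COLS) | {RESPONSE}
            covariates = [c for c in df.columns
                          if c not in skip and pd.api.types.is_numeric_dtype(df[c])]
        return cls(df.reset_index(drop=True), list(covariates), cd_max,
                   dict(meta or {}))


def _percent_transform(latent: np.ndarray, zero_inflation: float) -> np.ndarray:
    u = norm.cdf(latent)
    if zero_inflation > 0:
        v = 100.0 * (u - zero_inflation) / (1.0 - zero_inflation)
        return np.clip(v, 0.0, 100.0)
    return 100.0 * u


def _value_transform(spec: CovariateSpec, latent: np.ndarray) -> np.ndarray:
    if spec.kind == "percent":
        return _percent_transform(latent, spec.zero_inflation)
    # distance / positive: lognormal with median `scale`
    vals = spec.scale * np.exp(spec.log_sd * latent)
    if spec.zero_inflation > 0:
        vals[latent < norm.ppf(spec.zero_inflation)] = 0.0
    return vals


class StudyGenerator:
    """Holds the latent fields of one study so that sites and grids share
    them.  All randomness derives from ``config.seed`` through named
    substreams, giving stage-level reproducibility."""

    def __init__(self, config: StudyConfig):
        self.config = config
        ss = np.random.SeedSequence(config.seed)
        keys = ("fields", "coords", "species", "tree", "noise", "grid")
        children = ss.spawn(len(keys))
        self._rng = {k: np.random.default_rng(c) for k, c in zip(keys, children)}
        self._build_fields()

    def _build_fields(self):
        rng = self._rng["fields"]
        self._families = {}
        self._singles = {}
        for spec in self.config.covariates:
            if spec.buffer_radii_km:
                self._families[spec.name] = CorrelatedFamily(
                    rng, len(spec.buffer_radii_km), spec.corr_length_m,
                    spec.rank_corr_target)
            else:
                self._singles[spec.name] = LatentField(rng, spec.corr_length_m)

    def covariate_values(self, x, y) -> pd.DataFrame:
        """Evaluate every covariate at arbitrary coordinates."""
        out = {}
        for spec in self.config.covariates:
            if spec.buffer_radii_km:
                fam = self._families[spec.name]
                for k, col in enumerate(spec.columns):
                    out[col] = _value_transform(spec, fam.member(k, x, y))
            else:
                out[spec.name] = _value_transform(
                    spec, self._singles[spec.name](x, y))
        return pd.DataFrame(out)

    # -- sites -------------------------------------------------------------
    def generate_sites(self) -> SiteTable:
        cfg = self.config
        rng = self._rng["coords"]
        rows = []
        for zone in cfg.zones:
            n_z = cfg.sites_per_zone()[zone.name]
            xs = rng.uniform(zone.xmin, zone.xmax, n_z)
            ys = rng.uniform(zone.ymin, zone.ymax, n_z)
            rows.append(pd.DataFrame({"x": xs, "y": ys, "zone": zone.name}))
        df = pd.concat(rows, ignore_index=True)
        df.insert(0, "site_id", [f"s{i + 1:04d}" for i in range(len(df))])
        species = list(cfg.species_probs)
        df["moss_species"] = self._rng["species"].choice(
            species, size=len(df), p=list(cfg.species_probs.values()))
        trees = list(cfg.tree_probs)
        df["tree_cover"] = self._rng["tree"].choice(
            trees, size=len(df), p=list(cfg.tree_probs.values()))
        cov = self.covariate_values(df["x"].to_numpy(), df["y"].to_numpy())
        df = pd.concat([df, cov], axis=1)
        meta = {"n_covariates": cov.shape[1], "seed": cfg.seed}
        if cfg.n_sites < 2 * cov.shape[1]:
            meta["overfit_warning"] = True
            warnings.warn(
                f"{cfg.n_sites} sites for {cov.shape[1]} covariates: "
                "fewer than 2 observations per covariate (overfitting risk)",
                stacklevel=2)
        else:
            meta["overfit_warning"] = False
        return SiteTable(df, list(cov.columns), cfg.cd_max, meta)

    # -- response ----------------------------------------------------------
    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        cfg = self.config
        eta = np.full(len(table), cfg.true_alpha, float)
        for key, beta in cfg.true_betas.items():
            if ":" in key:
                col, level = key.split(":", 1)
                if col not in table.columns:
                    raise KeyError(f"categorical column {col!r} missing for effect {key!r}")
                eta += beta * (table[col] == level).to_numpy(float)
            else:
                if key not in table.columns:
                    raise KeyError(f"covariate {key!r} named in true_betas is absent")
                eta += beta * table[key].to_numpy(float)
        return eta

    def simulate_response(self, sites: SiteTable) -> SiteTable:
        cfg = self.config
        eta = self.linear_predictor(sites.data)
        eps = self._rng["noise"].normal(0.0, cfg.sigma, sites.n)
        y = cfg.cd_max * np.exp(-np.exp(eta + eps))
        df = sites.data.copy()
        df[RESPONSE] = y
        return SiteTable(df, list(sites.covariates), cfg.cd_max,
                         {**sites.meta, "sigma": cfg.sigma})

    # -- grid --------------------------------------------------------------
    def generate_grid(self, cell_size_m: float) -> pd.DataFrame:
        if cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        zones = list(self.config.zones)
        if not zones or all(z.area == 0 for z in zones):
            raise ValueError("empty study extent")
        xmin = min(z.xmin for z in zones)
        xmax = max(z.xmax for z in zones)
        ymin = min(z.ymin for z in zones)
        ymax = max(z.ymax for z in zones)
        nx = int(np.ceil((xmax - xmin) / cell_size_m))
        ny = int(np.ceil((ymax - ymin) / cell_size_m))
        cx = xmin + (np.arange(nx) + 0.5) * cell_size_m
        cy = ymin + (np.arange(ny) + 0.5) * cell_size_m
        gx, gy = np.meshgrid(cx, cy)
        gx, gy = gx.ravel(), gy.ravel()
        zone_label = np.full(gx.shape, "", dtype=object)
        for z in zones:
            mask = z.contains(gx, gy)
            zone_label[mask] = z.name
        keep = zone_label != ""
        grid = pd.DataFrame({"x": gx[keep], "y": gy[keep],
                             "zone": zone_label[keep]})
        cov = self.covariate_values(grid["x"].to_numpy(), grid["y"].to_numpy())
        grid = pd.concat([grid.reset_index(drop=True), cov], axis=1)
        grid.insert(0, "cell_id", np.arange(len(grid)))
        grid.attrs["cell_size_m"] = cell_size_m
        grid.attrs["n_cells"] = len(grid)
        return grid


# -- module-level convenience API (deterministic in config.seed) -----------

def generate_sites(config: StudyConfig) -> SiteTable:
    """Site table (without response) for the configured design."""
    return StudyGenerator(config).generate_sites()


def simulate_response(sites: SiteTable, config: StudyConfig) -> SiteTable:
    """Attach CLL-model responses Y = cd_max * exp(-exp(eta + eps))."""
    return StudyGenerator(config).simulate_response(sites)


def generate_grid(config: StudyConfig, cell_size_m: float) -> pd.DataFrame:
    """Regular prediction grid sharing the sites' latent covariate fields."""
    return StudyGenerator(config).generate_grid(cell_size_m)
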