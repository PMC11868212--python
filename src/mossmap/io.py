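"""CSV readers/writers with validation for site tables and stage outputs."""
from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import SiteTable, RESPONSE

PERCENT_PREFIXES = ("Forest", "Urban", "Industrial", "Pasture", "Agricultural",
                    "Fruits", "Vegetation", "Water", "Sea")


class SiteTableError(ValueError):
    pass


def write_site_table(sites: SiteTable, path) -> None:
    sites.data.to_csv(path, index=False)


def read_site_table(path, cd_max: float = 1.5, covariates=None,
                    required_covariates=None) -> SiteTable:
    """Load and validate a site-table CSV.

    Checks: required identifier columns present, response strictly inside
    (0, cd_max), land-use percentages in [0, 100], no missing values.
    Errors cite the offending CSV line numbers (header is line 1).
    """
    df = pd.read_csv(path)
    missing = [c for c in ("site_id", "x", "y", "zone") if c not in df.columns]
    if missing:
        raise SiteTableError(f"{path}: missing column(s) {missing}")
    if required_covariates:
        absent = [c for c in required_covariates if c not in df.columns]
        if absent:
            raise SiteTableError(f"{path}: missing covariate column(s) {absent}")

    def lines(mask):
        return (np.flatnonzero(mask) + 2).tolist()[:10]  # +2: header + 1-based

    na = df.isna().any(axis=1)
    if na.any():
        raise SiteTableError(f"{path}: missing values at line(s) {lines(na)}")
    if RESPONSE in df.columns:
        y = df[RESPONSE].to_numpy(float)
        bad = (y <= 0) | (y >= cd_max)
        if bad.any():
            raise SiteTableError(
                f"{path}: response outside (0, {cd_max}) at line(s) {lines(bad)}")
    table = SiteTable.from_frame(df, covariates=covariates, cd_max=cd_max)
    for col in table.covariates:
        if col.split("_")[0] in PERCENT_PREFIXES:
            vals = df[col].to_numpy(float)
            bad = (vals < 0) | (vals > 100)
            if bad.any():
                raise SiteTableError(
                    f"{path}: {col} outside [0, 100] at line(s) {lines(bad)}")
    return table


def write_report(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
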