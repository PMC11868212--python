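"""Covariate pre-selection: zero-proportion filter and Spearman collinearity filter.

Two screens run before any model selection:

1. **Zero filter** — a quantitative covariate is dropped when its proportion
   of exact zeros, on the rows in scope, is *strictly greater* than a
   threshold (default 0.95).  An overwhelming share of zeros makes the rare
   non-zero signal uninformative.
2. **Spearman filter** — (a) within each buffer family (``Forest_1``,
   ``Forest_5``, ...), members whose rank correlation exceeds the threshold
   (default 0.75) are collapsed onto the smallest-buffer member of each
   over-threshold connected component; (b) across families, while any pair
   of retained variables correlates above the threshold, the member with
   the larger mean absolute rank correlation to everything else retained is
   removed, starting from the worst-offending pair.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .synthetic import SiteTable

_FAMILY_RE = re.compile(r"^(?P<base>.+)_(?P<radius>\d+(?:\.\d+)?)$")

ZERO_FILTER = "zero_filter"
COLLINEAR_FAMILY = "collinear_family"
COLLINEAR_PAIR = "collinear_pair"


@dataclass
class ScreeningReport:
    """Outcome of the screening filters.

    ``removed`` holds ``(variable, reason, detail)`` tuples, where detail is
    the offending zero proportion or correlation; ``retained`` preserves the
    input column order.
    """

    removed: list = field(default_factory=list)
    retained: list = field(default_factory=list)
    threshold_zero: float = 0.95
    threshold_rho: float = 0.75

    @property
    def removed_names(self) -> list:
        return [name for name, _, _ in self.removed]

    def to_frame(self) -> pd.DataFrame:
        rows = [(v, "removed", reason, detail) for v, reason, detail in self.removed]
        rows += [(v, "retained", "", "") for v in self.retained]
        return pd.DataFrame(rows, columns=["variable", "status", "reason", "detail"])

    def check_partition(self, variables) -> None:
        if set(self.removed_names) | set(self.retained) != set(variables) or \
                set(self.removed_names) & set(self.retained):
            raise AssertionError("screening report does not partition the input")


def split_family(name: str):
    """Return (base, radius) for buffered names, (name, None) otherwise."""
    m = _FAMILY_RE.match(name)
    if m:
        return m.group("base"), float(m.group("radius"))
    return name, None


def zero_filter(sites: SiteTable, threshold: float = 0.95,
                mode: str = "pooled") -> ScreeningReport:
    """Drop quantitative covariates with too many exact zeros.

    ``mode="pooled"`` evaluates the zero proportion on all rows in the
    table (the natural choice for a model spanning every zone);
    ``mode="any_zone"`` removes a variable sparse in *any* single zone.
    Qualitative design columns are never considered.
    """
    if sites.n == 0:
        raise ValueError("empty site table")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    if mode not in ("pooled", "any_zone"):
        raise ValueError("mode must be 'pooled' or 'any_zone'")
    report = ScreeningReport(threshold_zero=threshold)
    df = sites.data
    for var in sites.covariates:
        vals = df[var].to_numpy(float)
        if mode == "pooled":
            prop = float(np.mean(vals == 0.0))
        else:
            prop = max(float(np.mean(vals[df["zone"] == z] == 0.0))
                       for z in df["zone"].unique())
        if prop > threshold:
            report.removed.append((var, ZERO_FILTER, prop))
        else:
            report.retained.append(var)
    report.check_partition(sites.covariates)
    return report


def _spearman_matrix(df: pd.DataFrame) -> pd.DataFrame:
    if df.shape[1] == 1:
        return pd.DataFrame([[1.0]], index=df.columns, columns=df.columns)
    rho = spearmanr(df.to_numpy(float)).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
    return pd.DataFrame(rho, index=df.columns, columns=df.columns)


def _components(nodes, edges):
    """Connected components of an undirected graph given as an edge list."""
    parent = {n: n for n in nodes}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in edges:
        parent[find(a)] = find(b)
    comps = {}
    for n in nodes:
        comps.setdefault(find(n), []).append(n)
    return list(comps.values())


def spearman_filter(sites: SiteTable, threshold: float = 0.75,
                    variables=None) -> ScreeningReport:
    """Collinearity screen; ``variables`` defaults to all covariates and is
    normally the retained list of :func:`zero_filter`."""
    if variables is None:
        variables = list(sites.covariates)
    variables = list(variables)
    report = ScreeningReport(threshold_rho=threshold)
    df = sites.data[variables]

    # constant columns have no defined rank correlation: remove up front
    live = []
    for var in variables:
        if df[var].nunique() <= 1:
            report.removed.append((var, COLLINEAR_PAIR, "undefined correlation"))
        else:
            live.append(var)

    if live:
        rho = _spearman_matrix(sites.data[live]).abs()

        # step 1: within-family collapse onto the smallest buffer
        families = {}
        for var in live:
            base, radius = split_family(var)
            if radius is not None:
                families.setdefault(base, []).append((radius, var))
        for base, members in families.items():
            names = [v for _, v in members]
            edges = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]
                     if rho.loc[a, b] > threshold]
            for comp in _components(names, edges):
                if len(comp) == 1:
                    continue
                keep = min(comp, key=lambda v: split_family(v)[1])
                for var in comp:
                    if var != keep:
                        detail = float(max(rho.loc[var, o] for o in comp if o != var))
                        report.removed.append((var, COLLINEAR_FAMILY, detail))
                        live.remove(var)

        # step 2: cross-family iterative removal, worst pair first
        while len(live) > 1:
            sub = rho.loc[live, live].to_numpy().copy()
            np.fill_diagonal(sub, 0.0)
            i, j = np.unravel_index(np.argmax(sub), sub.shape)
            worst = sub[i, j]
            if worst <= threshold:
                break
            pair = sorted([live[i], live[j]])
            means = {v: sub[live.index(v)].sum() / (len(live) - 1) for v in pair}
            # remove the more redundant member (larger mean |rho|)
            drop = max(pair, key=lambda v: (means[v], v))
            report.removed.append((drop, COLLINEAR_PAIR, float(worst)))
            live.remove(drop)

    report.retained = [v for v in variables if v in live]
    report.check_partition(variables)
    return report


def screen(sites: SiteTable, threshold_zero: float = 0.95,
           threshold_rho: float = 0.75, zero_mode: str = "pooled") -> ScreeningReport:
    """Run both filters in order and merge the reports."""
    zr = zero_filter(sites, threshold_zero, zero_mode)
    sr = spearman_filter(sites, threshold_rho, zr.retained)
    merged = ScreeningReport(
        removed=zr.removed + sr.removed,
        retained=sr.retained,
        threshold_zero=threshold_zero,
        threshold_rho=threshold_rho,
    )
    merged.check_partition(sites.covariates)
    return merged
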