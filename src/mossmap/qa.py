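"""Quality-assurance batch summaries for concentration series.

Reproduces the elementary statistics reported for certified reference
materials (CRMs) and survey batches: quartiles, coefficient of variation,
max/min ratio and the atypical-high outlier threshold

    threshold = Q3 + 1.5 * (Q3 - Q1),

plus the interval-overlap check of a measured CRM mean +/- SD against its
certified value.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class BatchSummary:
    n: int
    min: float
    q1: float
    median: float
    q3: float
    max: float
    mean: float
    sd: float
    cv_percent: float
    ratio_max_min: float
    atypical_threshold: float
    n_above_threshold: int
    ratio_defined: bool = True

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "n", "min", "q1", "median", "q3", "max", "mean", "sd",
            "cv_percent", "ratio_max_min", "atypical_threshold",
            "n_above_threshold")}


def atypical_threshold(q1: float, q3: float) -> float:
    """Outlier cutoff Q3 + 1.5 * (Q3 - Q1)."""
    return q3 + 1.5 * (q3 - q1)


def summarize_batch(values, quantile_method: str = "linear") -> BatchSummary:
    """Elementary statistics of a concentration batch.

    Quartiles use linear interpolation of order statistics by default; the
    convention is configurable because published thresholds recomputed from
    rounded quartiles are sensitive to it.  Values <= 0 leave the max/min
    ratio undefined (flagged) rather than raising.
    """
    v = np.asarray(values, float)
    if v.size < 1:
        raise ValueError("need at least one value")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75], method=quantile_method)
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    mean = float(v.mean())
    thr = atypical_threshold(float(q1), float(q3))
    ratio_defined = bool(v.min() > 0)
    return BatchSummary(
        n=int(v.size),
        min=float(v.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        max=float(v.max()),
        mean=mean,
        sd=sd,
        cv_percent=100.0 * sd / mean if mean != 0 else np.inf,
        ratio_max_min=float(v.max() / v.min()) if ratio_defined else np.nan,
        atypical_threshold=thr,
        n_above_threshold=int(np.sum(v > thr)),
        ratio_defined=ratio_defined,
    )


def crm_check(summary: BatchSummary, reference_mean: float,
              reference_sd: float) -> dict:
    """Pass iff [mean - sd, mean + sd] overlaps the certified interval."""
    lo_m, hi_m = summary.mean - summary.sd, summary.mean + summary.sd
    lo_r, hi_r = reference_mean - reference_sd, reference_mean + reference_sd
    passed = (lo_m <= hi_r) and (lo_r <= hi_m)
    return {
        "pass": bool(passed),
        "measured": (summary.mean, summary.sd),
        "reference": (reference_mean, reference_sd),
    }


#: Published quality-control statistics of the 2016 French moss survey
#: (445 samples) and its three CRM series (n = 15 each), used as numeric
#: inputs for recomputing the worked summary formulas.
PUBLISHED_QC = {
    "Moss M2": {"n": 15, "min": 0.433, "q1": 0.453, "median": 0.460,
                "q3": 0.477, "max": 0.558, "mean": 0.468, "sd": 0.028},
    "Moss M3": {"n": 15, "min": 0.093, "q1": 0.107, "median": 0.111,
                "q3": 0.113, "max": 0.127, "mean": 0.111, "sd": 0.009},
    "NIST 1573a": {"n": 15, "min": 1.350, "q1": 1.440, "median": 1.470,
                   "q3": 1.505, "max": 1.640, "mean": 1.473, "sd": 0.079},
    "BRAMM 2016": {"n": 445, "min": 0.029, "q1": 0.099, "median": 0.135,
                   "q3": 0.199, "max": 1.160, "mean": 0.174, "sd": 0.138},
}

#: Certified reference values (mean +/- SD, ug/g).
CRM_REFERENCE = {
    "Moss M2": (0.454, 0.019),
    "Moss M3": (0.106, 0.005),
    "NIST 1573a": (1.52, 0.04),
}
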