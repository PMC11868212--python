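"""Study configuration for the synthetic moss-biomonitoring design.

The configuration describes a national moss survey: sites scattered over a
set of rectangular biogeographical zones, a handful of moss species and
tree-cover classes with fixed sampling frequencies, and a battery of
quantitative covariates (buffered land-use percentages, distances to
infrastructure, modelled deposition / air concentration / soil metal)
generated from spatially correlated latent fields.  The response is a metal
concentration bounded in (0, cd_max) and driven by a complementary log-log
linear model.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import yaml

SPECIES = ("Hc", "Pp", "Tt", "Ps", "Hs")
TREE_COVERS = ("deciduous", "coniferous", "mixed_deciduous", "mixed_coniferous")

#: Reference levels used throughout model fitting (dummy coding).
REFERENCE_LEVELS = {
    "moss_species": "Hc",
    "tree_cover": "deciduous",
    "zone": "Alpine",
}


@dataclass(frozen=True)
class ZoneSpec:
    """Axis-aligned rectangular biogeographical zone.

    Coordinates are planar metres in an abstract CRS; ``weight`` is the
    zone's share of sites (need not be normalised).
    """

    name: str
    xmin: float
    xmax: float
    ymin: float
    ymax: float
    weight: float = 1.0

    def contains(self, x, y):
        return (
            (x >= self.xmin) & (x < self.xmax) & (y >= self.ymin) & (y < self.ymax)
        )

    @property
    def area(self) -> float:
        return (self.xmax - self.xmin) * (self.ymax - self.ymin)

    def overlaps(self, other: "ZoneSpec") -> bool:
        ox = min(self.xmax, other.xmax) - max(self.xmin, other.xmin)
        oy = min(self.ymax, other.ymax) - max(self.ymin, other.ymin)
        return ox > 0 and oy > 0


@dataclass(frozen=True)
class CovariateSpec:
    """One quantitative covariate or a family of buffered variants.

    Parameters
    ----------
    name:
        Base name; members of a buffer family are named ``{name}_{radius}``.
    kind:
        ``"percent"`` (land-use percentage in [0, 100]), ``"distance"``
        (metres, lognormal) or ``"positive"`` (lognormal, e.g. deposition).
    buffer_radii_km:
        Radii of the buffer family; empty means a single covariate.
    corr_length_m:
        Spatial correlation length of the underlying latent Gaussian field.
    rank_corr_target:
        Lower bound the pairwise Spearman correlation within the family
        should exceed; the latent fields are mixed with a margin above it.
    zero_inflation:
        Target proportion of exact zeros (spatially coherent, produced by
        thresholding the latent field).
    scale:
        Median of the lognormal for ``distance``/``positive`` kinds
        (ignored for ``percent``).
    log_sd:
        Log-scale standard deviation for ``distance``/``positive`` kinds.
    """

    name: str
    kind: str = "percent"
    buffer_radii_km: tuple = ()
    corr_length_m: float = 5e4
    rank_corr_target: float = 0.9
    zero_inflation: float = 0.0
    scale: float = 1.0
    log_sd: float = 0.5

    def __post_init__(self):
        if self.kind not in ("percent", "distance", "positive"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if not 0.0 <= self.zero_inflation < 1.0:
            raise ValueError("zero_inflation must lie in [0, 1)")

    @property
    def columns(self) -> list:
        if self.buffer_radii_km:
            return [f"{self.name}_{r:g}" for r in self.buffer_radii_km]
        return [self.name]


@dataclass
class StudyConfig:
    """Full description of one synthetic study."""

    n_sites: int
    zones: Sequence[ZoneSpec]
    species_probs: Mapping[str, float]
    tree_probs: Mapping[str, float]
    covariates: Sequence[CovariateSpec]
    true_alpha: float
    true_betas: Mapping[str, float]
    sigma: float
    cd_max: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.cd_max <= 0:
            raise ValueError("cd_max must be positive")
        for probs, what in ((self.species_probs, "species_probs"),
                            (self.tree_probs, "tree_probs")):
            total = float(sum(probs.values()))
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"{what} must sum to 1 (got {total!r})")
        zones = list(self.zones)
        for i, a in enumerate(zones):
            for b in zones[i + 1:]:
                if a.overlaps(b):
                    raise ValueError(f"zones {a.name!r} and {b.name!r} overlap")

    @property
    def covariate_columns(self) -> list:
        cols = []
        for spec in self.covariates:
            cols.extend(spec.columns)
        return cols

    @property
    def zone_names(self) -> list:
        return [z.name for z in self.zones]

    def sites_per_zone(self) -> dict:
        """Deterministic largest-remainder allocation of sites to zones."""
        weights = np.array([z.weight for z in self.zones], dtype=float)
        shares = self.n_sites * weights / weights.sum()
        counts = np.floor(shares).astype(int)
        remainder = self.n_sites - counts.sum()
        order = np.argsort(-(shares - counts))
        counts[order[:remainder]] += 1
        return {z.name: int(c) for z, c in zip(self.zones, counts)}

    # -- serialisation -----------------------------------------------------
    def to_yaml(self, path) -> None:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, (np.floating, float)):
                return float(obj)
            if isinstance(obj, (np.integer, int)) and not isinstance(obj, bool):
                return int(obj)
            return obj

        doc = {
            "n_sites": self.n_sites,
            "zones": [asdict(z) for z in self.zones],
            "species_probs": dict(self.species_probs),
            "tree_probs": dict(self.tree_probs),
            "covariates": [asdict(c) for c in self.covariates],
            "true_alpha": self.true_alpha,
            "true_betas": dict(self.true_betas),
            "sigma": self.sigma,
            "cd_max": self.cd_max,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(plain(doc), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc["zones"] = [ZoneSpec(**z) for z in doc["zones"]]
        doc["covariates"] = [
            CovariateSpec(**{**c, "buffer_radii_km": tuple(c.get("buffer_radii_km") or ())})
            for c in doc["covariates"]
        ]
        return cls(**doc)


def default_covariates() -> list:
    """Covariate battery emulating a national biomonitoring design:
    nine buffered land-use families, two buffered distance families,
    a family of cumulated deposition windows and three single covariates.
    """
    radii = (1, 5, 10, 15)
    specs = [
        CovariateSpec("Forest", "percent", radii, corr_length_m=6e4),
        CovariateSpec("Urban", "percent", radii, corr_length_m=4e4, zero_inflation=0.2),
        CovariateSpec("Industrial", "percent", radii, corr_length_m=4e4, zero_inflation=0.5),
        CovariateSpec("Pasture", "percent", radii, corr_length_m=6e4),
        CovariateSpec("Agricultural", "percent", radii, corr_length_m=8e4),
        CovariateSpec("Fruits", "percent", radii, corr_length_m=5e4, zero_inflation=0.6),
        CovariateSpec("Vegetation", "percent", radii, corr_length_m=6e4),
        CovariateSpec("Water", "percent", radii, corr_length_m=5e4, zero_inflation=0.4),
        CovariateSpec("Sea", "percent", radii, corr_length_m=1.2e5, zero_inflation=0.75),
        CovariateSpec("Railway", "distance", radii, corr_length_m=5e4,
                      scale=5_000.0, log_sd=0.8),
        CovariateSpec("Road", "distance", radii, corr_length_m=5e4,
                      scale=2_000.0, log_sd=0.8),
        CovariateSpec("EMEP_dep", "positive", (1, 3, 6, 9, 12),
                      corr_length_m=1.5e5, rank_corr_target=0.92,
                      scale=50.0, log_sd=0.4),
        CovariateSpec("EMEP_air", "positive", (), corr_length_m=1.5e5,
                      scale=0.5, log_sd=0.4),
        CovariateSpec("RMQS_tot", "positive", (), corr_length_m=8e4,
                      scale=0.3, log_sd=0.5),
        CovariateSpec("Altitude", "positive", (), corr_length_m=1e5,
                      scale=400.0, log_sd=0.7),
    ]
    return specs


def default_zones() -> list:
    # 900 x 900 km domain split into four rectangles; weights mirror the
    # observed per-zone site counts 220/147/49/29 of a 445-site campaign.
    return [
        ZoneSpec("Atlantic", 0.0, 500e3, 300e3, 900e3, weight=220),
        ZoneSpec("Continental", 500e3, 900e3, 300e3, 900e3, weight=147),
        ZoneSpec("Mediterranean", 0.0, 500e3, 0.0, 300e3, weight=49),
        ZoneSpec("Alpine", 500e3, 900e3, 0.0, 300e3, weight=29),
    ]


def default_true_betas() -> dict:
    """Ground-truth effects on the transformed scale z = ln(ln(cd_max/Y)).

    z decreases as the concentration rises, so a covariate that raises the
    metal load carries a *negative* coefficient here.
    """
    return {
        "EMEP_air": -0.55,          # per ug/m3-scale unit: more airborne Cd, more Cd in moss
        "RMQS_tot": -0.40,          # soil metal enrichment
        "Sea_10": 0.006,            # per percent: sea-salt washout lowers uptake
        "Agricultural_1": 0.004,
        "Urban_5": -0.005,
        "moss_species:Pp": 0.18,    # Pp accumulates less than the Hc reference
        "moss_species:Tt": 0.25,
        "moss_species:Ps": 0.12,
        "tree_cover:coniferous": -0.16,
        "tree_cover:mixed_coniferous": -0.12,
        "zone:Mediterranean": 0.20,
        "zone:Atlantic": -0.06,
    }


def default_study_config(seed: int = 0, n_sites: int = 445,
                         sigma: float = 0.3) -> StudyConfig:
    """The default synthetic campaign: 445 forest sites, four zones,
    species frequencies 227/186/27/4/1, four tree-cover classes and a
    55-column covariate battery."""
    species = dict(zip(SPECIES, np.array([227, 186, 27, 4, 1]) / 445.0))
    trees = dict(zip(TREE_COVERS, (0.40, 0.30, 0.15, 0.15)))
    return StudyConfig(
        n_sites=n_sites,
        zones=default_zones(),
        species_probs=species,
        tree_probs=trees,
        covariates=default_covariates(),
        true_alpha=0.35,
        true_betas=default_true_betas(),
        sigma=sigma,
        cd_max=1.5,
        seed=seed,
    )
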