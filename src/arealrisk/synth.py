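"""Synthetic-data generator for the full pipeline.

Emulates the statistical structure of an areal claims-data cohort at desk
scale: a regular square lattice of spatial units, log-normal unit
populations split into 5-year age band x sex strata by a stated age
pyramid, person-level observation windows with exponential censoring,
disease-specific first-event times from a Poisson process whose rate is a
configurable baseline multiplied by the relative risk of any planted
circular cluster, and Gaussian unit covariates whose means shift inside
planted clusters.

Defaults are a 20x20 lattice (400 units), ~200 persons per unit, a 6-year
study window, and a baseline rate of 20 events per 1000 person-years —
small enough to simulate in seconds, large enough that a planted RR of
1.5+ is recoverable by the scan statistic. The generator emits exactly the
tables the other modules consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .geo import UnitGeometry
from .incidence import AGE_BANDS, DAYS_PER_YEAR, SEXES

__all__ = [
    "PlantedCluster",
    "SimConfig",
    "simulate_geography",
    "simulate_persons",
    "simulate_covariates",
    "planted_members",
    "simulate_classification_table",
]

# a simple middle-heavy adult age pyramid over the 19 bands (sums to 1);
# adults dominate because the cohort is treated dental patients
AGE_PYRAMID = np.array(
    [0.04, 0.04, 0.045, 0.05, 0.06, 0.065, 0.07, 0.07, 0.07, 0.075,
     0.08, 0.075, 0.065, 0.055, 0.05, 0.04, 0.025, 0.015, 0.01]
)

RAW_COVARIATES = [
    "no_school", "university", "unemployment", "purchasing_power",
    "employment", "debtor", "net_income", "conservative_upscale",
    "nostalgic_middle", "precarious", "traditional",
    "inhabitants_per_household", "inhabitants_per_km2", "dentists_per_1000",
]


@dataclass
class PlantedCluster:
    """A circular region of elevated risk: units whose centroid lies within
    ``radius`` of ``center`` (lattice coordinates, meters) carry relative
    risk ``rr`` for ``disease``."""

    center: tuple[float, float]
    radius: float
    disease: str
    rr: float

    def __post_init__(self) -> None:
        if self.rr < 0:
            raise ValueError("relative risk must be non-negative")


@dataclass
class SimConfig:
    """Study-condition settings for the generator."""

    rows: int = 20
    cols: int = 20
    cell_size: float = 1000.0  # meters
    pop_median: float = 200.0
    pop_sigma: float = 0.35  # log-scale sd of unit populations
    baseline_rates: dict[str, float] = field(
        default_factory=lambda: {"caries": 20.0}
    )  # per 1000 person-years
    clusters: list[PlantedCluster] = field(default_factory=list)
    study_years: float = 6.0
    censor_hazard: float = 0.02  # per person-year
    covariate_shift: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ValueError("lattice must be at least 2x2")
        for d, r in self.baseline_rates.items():
            if r <= 0:
                raise ValueError(f"baseline rate for {d!r} must be positive")

    @property
    def diseases(self) -> list[str]:
        return list(self.baseline_rates)


def _unit_ids(cfg: SimConfig) -> list[str]:
    return [f"U{r:03d}{c:03d}" for r in range(cfg.rows) for c in range(cfg.cols)]


def _lattice_centers(cfg: SimConfig) -> np.ndarray:
    centers = [
        ((c + 0.5) * cfg.cell_size, (r + 0.5) * cfg.cell_size)
        for r in range(cfg.rows)
        for c in range(cfg.cols)
    ]
    return np.asarray(centers)


def planted_members(cfg: SimConfig, disease: str) -> set[str]:
    """Units inside any planted cluster for the disease."""
    ids = _unit_ids(cfg)
    centers = _lattice_centers(cfg)
    members: set[str] = set()
    for cl in cfg.clusters:
        if cl.disease != disease:
            continue
        d = np.hypot(centers[:, 0] - cl.center[0], centers[:, 1] - cl.center[1])
        members |= {ids[i] for i in np.flatnonzero(d <= cl.radius)}
    return members


def _unit_rr(cfg: SimConfig, disease: str) -> pd.Series:
    ids = _unit_ids(cfg)
    rr = pd.Series(1.0, index=ids)
    for uid in planted_members(cfg, disease):
        for cl in cfg.clusters:
            if cl.disease == disease:
                rr[uid] = cl.rr
    return rr


def simulate_geography(
    cfg: SimConfig,
) -> tuple[list[UnitGeometry], pd.DataFrame]:
    """Square-lattice unit polygons plus a population grid-cell table.

    Each unit gets four grid cells (its quadrants) whose populations split
    the unit's log-normal total with small Dirichlet jitter, so the
    population-weighted centroid is near but not exactly at the geometric
    center. Deterministic given cfg.seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[0])
    ids = _unit_ids(cfg)
    s = cfg.cell_size
    units = []
    grid_rows = []
    pops = cfg.pop_median * rng.lognormal(0.0, cfg.pop_sigma, size=len(ids))
    k = 0
    for r in range(cfg.rows):
        for c in range(cfg.cols):
            x0, y0 = c * s, r * s
            poly = Polygon([(x0, y0), (x0 + s, y0), (x0 + s, y0 + s), (x0, y0 + s)])
            units.append(UnitGeometry(unit_id=ids[k], polygon=poly))
            shares = rng.dirichlet(np.full(4, 8.0))
            quads = [
                (x0 + 0.25 * s, y0 + 0.25 * s),
                (x0 + 0.75 * s, y0 + 0.25 * s),
                (x0 + 0.25 * s, y0 + 0.75 * s),
                (x0 + 0.75 * s, y0 + 0.75 * s),
            ]
            unit_pop = max(1, int(round(pops[k])))
            cell_pops = np.round(shares * unit_pop).astype(int)
            cell_pops[0] += unit_pop - cell_pops.sum()  # conserve the total
            for (qx, qy), cp in zip(quads, cell_pops):
                grid_rows.append((qx, qy, max(int(cp), 0), ids[k]))
            k += 1
    grid = pd.DataFrame(grid_rows, columns=["x", "y", "population", "unit_id"])
    return units, grid


def simulate_persons(cfg: SimConfig, grid: pd.DataFrame) -> pd.DataFrame:
    """Person-level observation windows and first-event dates per disease.

    One person per head of unit population. Entry at study start;
    censoring exponential at cfg.censor_hazard per year, truncated at the
    study end. Each disease's first-event time is exponential with rate
    baseline x RR(unit) per person-year; events after exit are unobserved.
    Age bands are drawn from the stated pyramid, sex is balanced.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[1])
    unit_pop = grid.groupby("unit_id", sort=True)["population"].sum()
    n = int(unit_pop.sum())
    unit_of = np.repeat(unit_pop.index.to_numpy(), unit_pop.to_numpy().astype(int))
    start = pd.Timestamp("2016-01-01")
    censor = rng.exponential(1.0 / cfg.censor_hazard, size=n)
    followup = np.minimum(censor, cfg.study_years)
    band_idx = rng.choice(len(AGE_BANDS), size=n, p=AGE_PYRAMID)
    age = 5 * band_idx + rng.integers(0, 5, size=n)
    sex = rng.choice(SEXES, size=n)
    df = pd.DataFrame(
        {
            "person_id": [f"P{i:07d}" for i in range(n)],
            "unit_id": unit_of,
            "entry": start,
            "exit": start + pd.to_timedelta(np.round(followup * DAYS_PER_YEAR), unit="D"),
            "sex": sex,
            "birth_year": start.year - age,
        }
    )
    for disease, base in cfg.baseline_rates.items():
        rr = _unit_rr(cfg, disease).reindex(unit_of).to_numpy()
        rate = (base / 1000.0) * rr  # per person-year
        with np.errstate(divide="ignore"):
            t_event = np.where(
                rate > 0, rng.exponential(1.0, size=n) / np.where(rate > 0, rate, 1.0), np.inf
            )
        observed = t_event <= followup
        dates = pd.Series(pd.NaT, index=df.index, dtype="datetime64[ns]")
        dates[observed] = start + pd.to_timedelta(
            np.round(t_event[observed] * DAYS_PER_YEAR), unit="D"
        )
        df[disease] = dates
    return df


def simulate_covariates(
    cfg: SimConfig, cluster_members: set[str]
) -> pd.DataFrame:
    """Raw unit covariates: standard-normal columns plus the configured
    mean shift inside the planted cluster (cfg.covariate_shift maps raw
    variable name -> shift in sd units). Deterministic given cfg.seed."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[2])
    ids = _unit_ids(cfg)
    member = np.array([uid in cluster_members for uid in ids], dtype=float)
    data = {}
    for var in RAW_COVARIATES:
        shift = cfg.covariate_shift.get(var, 0.0)
        data[var] = rng.standard_normal(len(ids)) + shift * member
    out = pd.DataFrame(data, index=pd.Index(ids, name="unit_id"))
    return out


def simulate_classification_table(
    n: int = 2000,
    coef: dict[str, float] | None = None,
    intercept: float = -2.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Feature table whose binary label follows a logistic model.

    Standard-normal features named after the model feature set; the label
    is Bernoulli with logit = intercept + sum coef_j x_j. Used to test
    that classifier training and permutation importance recover planted
    determinants.
    """
    from .riskmodel import FEATURE_COLUMNS

    coef = coef or {"income": -2.0, "inhabitants_per_km2": -1.5}
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.standard_normal((n, len(FEATURE_COLUMNS))), columns=FEATURE_COLUMNS
    )
    logit = intercept + sum(c * X[v] for v, c in coef.items())
    p = 1.0 / (1.0 + np.exp(-logit))
    X["label"] = rng.random(n) < p
    return X
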