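"""Person-time incidence rates, exact Poisson intervals, direct
standardization, and local empirical Bayes smoothing.

Rates are reported per 1000 person-years throughout. Person-time uses the
ACT/365.25 day-count convention. Diseases are handled independently: a
person stays at risk for disease B after an event of disease A, so
person-time denominators differ per disease.
"""

from __future__ import annotations

import json
import logging
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .geo import ContiguityWeights

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
RATE_SCALE = 1000.0

AGE_BANDS = [
    "0-4", "5-9", "10-14", "15-19", "20-24", "25-29", "30-34", "35-39",
    "40-44", "45-49", "50-54", "55-59", "60-64", "65-69", "70-74", "75-79",
    "80-84", "85-89", "90+",
]
SEXES = ["F", "M"]

__all__ = [
    "person_time",
    "raw_rate",
    "exact_poisson_ci",
    "direct_standardize",
    "local_eb_smooth",
    "age_band",
    "esp2013_weights",
    "rate_table",
    "read_persons_csv",
]


def age_band(age: float | np.ndarray) -> np.ndarray:
    """5-year age band label, top-coded at 90+."""
    age = np.asarray(age)
    idx = np.clip((age // 5).astype(int), 0, 18)
    return np.asarray(AGE_BANDS, dtype=object)[idx]


def esp2013_weights() -> dict[tuple[str, str], float]:
    """2013 European Standard Population stratum weights (age band x sex).

    The ESP age vector is sex-independent; each sex receives half the age
    band's weight. Weights sum to 1.
    """
    payload = json.loads(
        resources.files("arealrisk.data").joinpath("esp2013.json").read_text()
    )
    bands = payload["age_bands"]
    total = 2.0 * sum(bands.values())
    return {
        (band, sex): w / total for band, w in bands.items() for sex in SEXES
    }


def read_persons_csv(path, diseases: list[str]) -> pd.DataFrame:
    """Read a person table: person_id, unit_id, entry, exit, sex, birth_year
    and one event-date column per disease (named after the disease)."""
    date_cols = ["entry", "exit", *diseases]
    df = pd.read_csv(path, dtype={"unit_id": str, "person_id": str})
    for c in date_cols:
        df[c] = pd.to_datetime(df[c], errors="coerce")
    return df


def person_time(
    persons: pd.DataFrame, disease: str, *, by_stratum: bool = False
) -> pd.DataFrame:
    """Cases Y and person-years T per unit (optionally per age-sex stratum).

    Each person contributes (min(event, exit) - entry) / 365.25 years and at
    most one case of the disease; follow-up for this disease stops at the
    first disease-specific event. Records with an event before entry or
    exit before entry are rejected and logged.

    ``persons`` columns: person_id, unit_id, entry, exit, sex, birth_year,
    plus a datetime column named after each disease (NaT = no event).
    """
    if persons.empty:
        cols = ["unit_id", "Y", "T"] + (["age_band", "sex"] if by_stratum else [])
        return pd.DataFrame(columns=cols)
    df = persons.copy()
    bad = (df["exit"] < df["entry"]) | (
        df[disease].notna() & (df[disease] < df["entry"])
    )
    if bad.any():
        logger.warning(
            "rejected %d person record(s) with event/exit before entry", int(bad.sum())
        )
        df = df.loc[~bad]
    end = df[[disease, "exit"]].min(axis=1)
    has_event = df[disease].notna() & (df[disease] <= df["exit"])
    years = (end - df["entry"]).dt.days / DAYS_PER_YEAR
    out = pd.DataFrame(
        {
            "unit_id": df["unit_id"].to_numpy(),
            "Y": has_event.astype(int).to_numpy(),
            "T": years.to_numpy(),
        }
    )
    keys = ["unit_id"]
    if by_stratum:
        # age at entry defines the stratum; adequate for a short window
        age = df["entry"].dt.year.to_numpy() - df["birth_year"].to_numpy()
        out["age_band"] = age_band(age)
        out["sex"] = df["sex"].to_numpy()
        keys += ["age_band", "sex"]
    agg = out.groupby(keys, sort=True, as_index=False).sum(numeric_only=True)
    return agg


def raw_rate(Y: float | np.ndarray, T: float | np.ndarray) -> float | np.ndarray:
    """Incidence rate per 1000 person-years: 1000 * Y / T."""
    Y = np.asarray(Y, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("person-time T must be positive")
    out = RATE_SCALE * Y / T
    return float(out) if out.ndim == 0 else out


def exact_poisson_ci(
    Y: int | np.ndarray, T: float | np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Exact (chi-square) two-sided Poisson confidence bounds for the rate.

    Bounds on the Poisson mean are Y_l = chi2_{2Y, alpha/2} / 2 and
    Y_u = chi2_{2(Y+1), 1-alpha/2} / 2 (lower bound 0 when Y = 0); dividing
    by person-time and scaling gives bounds per 1000 person-years.
    """
    Y = np.atleast_1d(np.asarray(Y))
    T = np.atleast_1d(np.asarray(T, dtype=float))
    if np.any(Y < 0) or np.any(Y != np.floor(Y)):
        raise ValueError("Y must be a non-negative integer count")
    if np.any(T <= 0):
        raise ValueError("person-time T must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    Y = Y.astype(float)
    lower = np.where(Y > 0, stats.chi2.ppf(alpha / 2, 2 * Y) / 2.0, 0.0)
    upper = stats.chi2.ppf(1 - alpha / 2, 2 * (Y + 1)) / 2.0
    lo = RATE_SCALE * lower / T
    hi = RATE_SCALE * upper / T
    if lo.size == 1:
        return float(lo[0]), float(hi[0])
    return lo, hi


def direct_standardize(
    stratum_counts: pd.DataFrame,
    std_weights: dict[tuple[str, str], float] | None = None,
    *,
    renormalize_missing: bool = False,
) -> float:
    """Directly age-sex standardized rate per 1000 person-years.

    ``stratum_counts`` carries columns age_band, sex, Y, T. Standard weights
    (default ESP2013) are normalized to sum to 1; the adjusted rate is
    sum_s w_s * 1000 * Y_s / T_s. Strata present in the standard but absent
    (or with zero person-time) in the data contribute zero with a warning;
    with ``renormalize_missing`` the remaining weights are rescaled to 1
    instead.
    """
    if std_weights is None:
        std_weights = esp2013_weights()
    total_w = sum(std_weights.values())
    if total_w <= 0:
        raise ValueError("standard population weights must sum to a positive constant")
    counts = stratum_counts.set_index(["age_band", "sex"])
    if counts.empty or counts["T"].sum() <= 0:
        raise ValueError("no observed person-time in any stratum")
    extra = set(counts.index) - set(std_weights)
    if extra:
        raise ValueError(f"strata absent from the standard population: {sorted(extra)}")
    acc = 0.0
    used_w = 0.0
    missing = []
    for stratum, w in std_weights.items():
        if stratum in counts.index and counts.loc[stratum, "T"] > 0:
            acc += w * RATE_SCALE * counts.loc[stratum, "Y"] / counts.loc[stratum, "T"]
            used_w += w
        else:
            missing.append(stratum)
    if missing:
        logger.warning(
            "%d standard-population strata have no observed person-time", len(missing)
        )
    denom = used_w if renormalize_missing else total_w
    return float(acc / denom)


def local_eb_smooth(
    rates: pd.Series,
    populations: pd.Series,
    W: ContiguityWeights,
) -> pd.Series:
    """Local empirical Bayes smoothing of per-unit rates (per 1000).

    Each unit's raw rate is shrunk toward the population-weighted mean rate
    m_i of its neighborhood (the unit plus its first-order rook neighbors).
    The shrinkage factor C_i = s2_i / (s2_i + m_i / nbar_i) uses the local
    population-weighted rate variance s2_i and the local mean population
    nbar_i, so rates backed by small populations move most; smoothed_i =
    m_i + C_i (raw_i - m_i). Computation runs on the per-person-year scale
    so m/nbar is the Poisson variance of a rate estimate. Island units pass
    through unsmoothed.
    """
    ids = list(rates.index)
    smoothed = {}
    r = rates / RATE_SCALE  # per person-year
    for uid in ids:
        nbrs = W.neighbors.get(uid, [])
        if not nbrs:
            smoothed[uid] = float(rates[uid])
            continue
        hood = [uid] + [j for j in nbrs if j in rates.index]
        rv = r.loc[hood].to_numpy(dtype=float)
        pv = populations.loc[hood].to_numpy(dtype=float)
        ptot = pv.sum()
        if ptot <= 0:
            smoothed[uid] = float(rates[uid])
            continue
        m = float((pv * rv).sum() / ptot)
        s2 = float((pv * (rv - m) ** 2).sum() / ptot)
        nbar = float(pv.mean())
        denom = s2 + (m / nbar if nbar > 0 else 0.0)
        C = s2 / denom if denom > 0 else 0.0
        smoothed[uid] = RATE_SCALE * (m + C * (float(r[uid]) - m))
    out = pd.Series(smoothed, name="rate_smoothed")
    return out.reindex(rates.index)


def rate_table(
    persons: pd.DataFrame,
    diseases: list[str],
    *,
    alpha: float = 0.05,
    std_weights: dict[tuple[str, str], float] | None = None,
    rook_weights: ContiguityWeights | None = None,
    populations: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-unit, per-disease rate table: Y, T, raw rate, exact Poisson CI,
    directly standardized rate (from global stratum rates), and, when rook
    weights and populations are supplied, the locally smoothed rate."""
    frames = []
    for disease in diseases:
        counts = person_time(persons, disease)
        if counts.empty:
            continue
        counts = counts[counts["T"] > 0].copy()
        counts["disease"] = disease
        counts["rate"] = raw_rate(counts["Y"], counts["T"])
        lo, hi = exact_poisson_ci(
            counts["Y"].to_numpy(), counts["T"].to_numpy(), alpha
        )
        counts["rate_lo"], counts["rate_hi"] = lo, hi
        strat = person_time(persons, disease, by_stratum=True)
        strat_global = strat.groupby(["age_band", "sex"], as_index=False)[
            ["Y", "T"]
        ].sum()
        counts["rate_adj"] = direct_standardize(strat_global, std_weights)
        if rook_weights is not None and populations is not None:
            rates = counts.set_index("unit_id")["rate"]
            pops = populations.reindex(rates.index).fillna(0.0)
            counts["rate_smoothed"] = local_eb_smooth(
                rates, pops, rook_weights
            ).to_numpy()
        frames.append(counts)
    if not frames:
        return pd.DataFrame(
            columns=["unit_id", "Y", "T", "disease", "rate", "rate_lo", "rate_hi", "rate_adj"]
        )
    return pd.concat(frames, ignore_index=True)
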