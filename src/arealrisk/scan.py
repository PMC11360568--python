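"""Kulldorff's circular discrete-Poisson spatial scan statistic.

Candidate windows are circles centered on unit centroids (here,
population-weighted centroids): for each center, units are accumulated in
order of Euclidean distance, and every prefix whose share of the
expectation basis lies within configured population bounds forms a window.
For a window Z with observed cases c, expected cases e (proportional to
the window's share of the basis) and C total cases, the high-rate
log-likelihood ratio is

    llr(Z) = c ln(c/e) + (C - c) ln((C - c)/(C - e))   if c > e, else 0.

The window maximizing llr is the primary cluster; non-overlapping
runners-up are secondary clusters. Significance comes from Monte-Carlo
replication: cases are redistributed multinomially proportional to the
basis, and each window's llr is ranked against the replicate maxima,
p = (1 + rank) / (1 + nsim). The cluster relative risk is

    RR = (o/e) / ((O - o)/(O - e)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScanConfig",
    "Window",
    "ClusterResult",
    "candidate_windows",
    "poisson_llr",
    "monte_carlo_p",
    "relative_risk",
    "scan",
]


@dataclass
class ScanConfig:
    """Scan-window and inference settings.

    min/max_pop_frac bound the window's share of the population at risk
    (defaults 0.5% and 10%); nsim Monte-Carlo replicates (999; 0 disables
    inference); clusters with p < alpha are reported as significant (1%).
    Only elevated-rate windows are scanned.
    """

    min_pop_frac: float = 0.005
    max_pop_frac: float = 0.10
    nsim: int = 999
    alpha: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.min_pop_frac <= self.max_pop_frac <= 1:
            raise ValueError("need 0 < min_pop_frac <= max_pop_frac <= 1")
        if self.nsim != 0 and self.nsim < 99:
            raise ValueError("nsim must be 0 (no inference) or >= 99")


@dataclass
class Window:
    """A circular candidate window: member units in distance order."""

    center: str
    radius: float
    members: list[str]
    member_idx: np.ndarray
    basis: float  # window share basis (population or person-time)
    basis_frac: float


@dataclass
class ClusterResult:
    window: Window
    observed: float
    expected: float
    llr: float
    p_value: float
    rr: float
    rank: str
    extras: dict = field(default_factory=dict)


def poisson_llr(c: float, e: float, C: float) -> float:
    """High-rate Poisson scan log-likelihood ratio (0 when c <= e)."""
    if e <= 0:
        raise ValueError("expected count e must be positive")
    if e >= C:
        raise ValueError("expected count e must be below the case total C")
    if not 0 <= c <= C:
        raise ValueError("observed count c must lie in [0, C]")
    if c <= e:
        return 0.0
    inside = c * np.log(c / e)
    out_c = C - c
    outside = out_c * np.log(out_c / (C - e)) if out_c > 0 else 0.0
    return float(inside + outside)


def _llr_vec(c: np.ndarray, e: np.ndarray, C: float) -> np.ndarray:
    """Vectorized high-rate llr with the 0*ln(0) = 0 convention."""
    c = np.asarray(c, dtype=float)
    e = np.asarray(e, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        inside = np.where(c > 0, c * np.log(c / e), 0.0)
        rem = C - c
        outside = np.where(rem > 0, rem * np.log(rem / (C - e)), 0.0)
    return np.where(c > e, inside + outside, 0.0)


def relative_risk(o: float, e: float, O: float) -> float:
    """Cluster relative risk (o/e) / ((O-o)/(O-e)); inf when o = O."""
    if not 0 < e < O:
        raise ValueError("need 0 < e < O")
    if not 0 <= o <= O:
        raise ValueError("need 0 <= o <= O")
    if o == O:
        return float("inf")
    return float((o / e) / ((O - o) / (O - e)))


def candidate_windows(
    centroids: pd.DataFrame, basis: pd.Series, cfg: ScanConfig
) -> list[Window]:
    """Enumerate deduplicated circular windows.

    ``centroids``: frame indexed by unit_id with columns x, y.
    ``basis``: per-unit expectation basis (population or person-time).
    For each center, units join in order of centroid distance; distance
    ties join atomically. A window is emitted at every prefix whose basis
    fraction lies within [min_pop_frac, max_pop_frac]; identical member
    sets from different centers are reported once (first center kept).
    """
    ids = list(centroids.index)
    if len(ids) < 2:
        raise ValueError("need at least 2 units")
    b = basis.reindex(ids).to_numpy(dtype=float)
    if b.sum() <= 0:
        raise ValueError("expectation basis must be positive overall")
    xy = centroids[["x", "y"]].to_numpy(dtype=float)
    btot = b.sum()
    seen: set[frozenset] = set()
    windows: list[Window] = []
    for ci in range(len(ids)):
        d = np.hypot(xy[:, 0] - xy[ci, 0], xy[:, 1] - xy[ci, 1])
        order = np.argsort(d, kind="stable")
        d_sorted = d[order]
        csum = np.cumsum(b[order])
        k = 0
        n = len(ids)
        while k < n:
            # ties join atomically: advance to the last index at this distance
            j = k
            while j + 1 < n and d_sorted[j + 1] == d_sorted[k]:
                j += 1
            frac = csum[j] / btot
            if frac > cfg.max_pop_frac:
                break
            if frac >= cfg.min_pop_frac:
                key = frozenset(order[: j + 1].tolist())
                if key not in seen:
                    seen.add(key)
                    member_idx = order[: j + 1].copy()
                    windows.append(
                        Window(
                            center=ids[ci],
                            radius=float(d_sorted[j]),
                            members=[ids[t] for t in member_idx],
                            member_idx=member_idx,
                            basis=float(csum[j]),
                            basis_frac=float(frac),
                        )
                    )
            k = j + 1
    return windows


def monte_carlo_p(
    llr_obs: float | np.ndarray,
    case_total: int,
    basis: np.ndarray,
    windows: list[Window],
    nsim: int,
    seed: int | None = None,
) -> np.ndarray:
    """Monte-Carlo p-values against the null maximum-llr distribution.

    Each replicate redistributes the case total multinomially over units
    proportional to the basis and records the maximum llr over all
    windows; p = (1 + #{max_llr_sim >= llr_obs}) / (1 + nsim).
    """
    if nsim < 99:
        raise ValueError("nsim must be at least 99")
    sims = null_max_llr(case_total, basis, windows, nsim, seed)
    obs = np.atleast_1d(np.asarray(llr_obs, dtype=float))
    p = (1 + (sims[None, :] >= obs[:, None]).sum(axis=1)) / (1 + nsim)
    return p if np.ndim(llr_obs) else float(p[0])


def null_max_llr(
    case_total: int,
    basis: np.ndarray,
    windows: list[Window],
    nsim: int,
    seed: int | None = None,
) -> np.ndarray:
    """Null distribution of the scan maximum llr (one value per replicate)."""
    basis = np.asarray(basis, dtype=float)
    probs = basis / basis.sum()
    btot = basis.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(case_total, probs, size=nsim)  # (nsim, n)
    # group windows by center to reuse prefix cumsums
    by_center: dict[str, list[Window]] = {}
    for w in windows:
        by_center.setdefault(w.center, []).append(w)
    sims = np.zeros(nsim)
    C = float(case_total)
    for wins in by_center.values():
        longest = max(wins, key=lambda w: len(w.member_idx))
        order = longest.member_idx
        pref = counts[:, order].cumsum(axis=1)  # (nsim, len(order))
        sizes = np.array([len(w.member_idx) for w in wins])
        e = np.array([C * w.basis / btot for w in wins])
        # all windows of this center are prefixes of the longest one's order
        c_mat = pref[:, sizes - 1]  # (nsim, nwin)
        llrs = _llr_vec(c_mat, e[None, :], C)
        np.maximum(sims, llrs.max(axis=1), out=sims)
    return sims


def scan(
    case_counts: pd.Series,
    centroids: pd.DataFrame,
    cfg: ScanConfig | None = None,
    seed: int | None = None,
    *,
    basis: pd.Series | None = None,
    max_secondary: int = 10,
) -> list[ClusterResult]:
    """Full spatial scan: primary and non-overlapping secondary clusters.

    ``case_counts``: observed cases per unit_id. ``basis``: expectation
    basis per unit (person-time or population); defaults to person-time if
    a 'T' column exists in ``centroids``, otherwise it must be supplied.
    The primary cluster maximizes the llr; secondaries follow in
    decreasing llr among windows sharing no unit with any higher-ranked
    reported cluster. With cfg.nsim > 0, Monte-Carlo p-values are attached
    and only the primary plus secondaries with p < cfg.alpha are returned;
    with nsim = 0 p-values are NaN and the llr ranking alone is reported.
    """
    cfg = cfg or ScanConfig()
    if basis is None:
        if "T" in centroids.columns:
            basis = centroids["T"]
        else:
            raise ValueError("supply an expectation basis (person-time or population)")
    ids = list(centroids.index)
    cases = case_counts.reindex(ids).fillna(0.0).to_numpy(dtype=float)
    b = basis.reindex(ids).to_numpy(dtype=float)
    C = float(cases.sum())
    if C <= 0:
        raise ValueError("no cases observed")
    windows = candidate_windows(centroids, basis, cfg)
    if not windows:
        import logging

        logging.getLogger(__name__).warning(
            "no window satisfies the population-fraction bounds"
        )
        return []
    btot = b.sum()
    obs = np.array([cases[w.member_idx].sum() for w in windows])
    exp = np.array([C * w.basis / btot for w in windows])
    llrs = _llr_vec(obs, exp, C)

    if cfg.nsim > 0:
        sims = null_max_llr(int(round(C)), b, windows, cfg.nsim, seed)
    else:
        sims = None

    order = np.argsort(-llrs, kind="stable")
    taken: set[str] = set()
    results: list[ClusterResult] = []
    for rank_pos in order:
        w = windows[rank_pos]
        if taken & set(w.members):
            continue
        if llrs[rank_pos] <= 0 and results:
            break
        if sims is not None:
            p = float((1 + (sims >= llrs[rank_pos]).sum()) / (1 + cfg.nsim))
        else:
            p = float("nan")
        is_primary = not results
        if not is_primary:
            if sims is not None and p >= cfg.alpha:
                continue
            if len(results) > max_secondary:
                break
        o, e = float(obs[rank_pos]), float(exp[rank_pos])
        rr = relative_risk(o, e, C) if 0 < e < C else float("nan")
        results.append(
            ClusterResult(
                window=w,
                observed=o,
                expected=e,
                llr=float(llrs[rank_pos]),
                p_value=p,
                rr=rr,
                rank="primary" if is_primary else f"secondary-{len(results)}",
            )
        )
        taken |= set(w.members)
    return results


def clusters_to_frame(results: list[ClusterResult]) -> pd.DataFrame:
    """Flatten scan results into the report table."""
    rows = []
    for r in results:
        rows.append(
            {
                "rank": r.rank,
                "center_unit": r.window.center,
                "radius_m": r.window.radius,
                "n_units": len(r.window.members),
                "observed": r.observed,
                "expected": r.expected,
                "RR": r.rr,
                "llr": r.llr,
                "p": r.p_value,
                "members": ";".join(r.window.members),
            }
        )
    return pd.DataFrame(rows)
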