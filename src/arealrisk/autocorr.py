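"""Global and local Moran's I spatial autocorrelation with permutation inference.

Global Moran's I compares each unit's deviation from the overall mean with
the deviations of its contiguity neighbors:

    I = (sum_ij w_ij z_i z_j / S0) / (sum_i z_i^2 / n),  z = x - xbar.

Under no spatial autocorrelation E[I] = -1/(n-1). Local Moran's I_i
decomposes the global statistic per unit; the standard mean-deviation form
(deviations scaled by m2 = sum z^2 / n) is used so that quadrant labels
are well-defined and sum_i I_i / n recovers the global I under
row-standardized weights. A literal raw-value form is available via
``scale="raw"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import ContiguityWeights

__all__ = [
    "MoranResult",
    "global_moran",
    "moran_permutation_test",
    "local_moran",
    "moran_scatter_data",
]


@dataclass
class MoranResult:
    I: float
    expected: float
    z_norm: float
    p_norm: float
    z_rand: float
    p_rand: float
    n: int
    s0: float


def _aligned(x: pd.Series, W: ContiguityWeights) -> tuple[np.ndarray, np.ndarray, list[str]]:
    ids = [i for i in W.ids if i in x.index and W.neighbors[i]]
    islands = set(W.islands)
    if islands:
        ids = [i for i in ids if i not in islands]
    sub = {i: [j for j in W.neighbors[i] if j in set(ids)] for i in ids}
    # rebuild weights on the retained ids, preserving standardization mode
    Wsub = ContiguityWeights(
        neighbors=sub, order=W.order, row_standardized=W.row_standardized
    )
    mat = Wsub.to_matrix(ids)
    return x.loc[ids].to_numpy(dtype=float), mat, ids


def _moran_stat(z: np.ndarray, Wm: np.ndarray) -> float:
    n = z.size
    s0 = Wm.sum()
    m2 = (z @ z) / n
    return float((z @ Wm @ z) / s0 / m2)


def global_moran(x: pd.Series, W: ContiguityWeights) -> MoranResult:
    """Global Moran's I with analytic z-values under the normality and
    randomization null variances. Island units are excluded (statistic
    undefined without neighbors)."""
    v, Wm, ids = _aligned(x, W)
    n = len(ids)
    if n < 3:
        raise ValueError("global Moran's I needs at least 3 non-island units")
    z = v - v.mean()
    if np.allclose(z, 0):
        raise ValueError("x is constant; Moran's I undefined (zero variance)")
    s0 = Wm.sum()
    I = _moran_stat(z, Wm)
    EI = -1.0 / (n - 1)

    s1 = 0.5 * ((Wm + Wm.T) ** 2).sum()
    s2 = ((Wm.sum(axis=1) + Wm.sum(axis=0)) ** 2).sum()
    # normality-assumption variance
    var_n = (n * n * s1 - n * s2 + 3 * s0 * s0) / ((n * n - 1) * s0 * s0) - EI**2
    # randomization variance
    m2 = (z @ z) / n
    m4 = (z**4).sum() / n
    b2 = m4 / (m2 * m2)
    num = n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0) - b2 * (
        (n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0
    )
    var_r = num / ((n - 1) * (n - 2) * (n - 3) * s0 * s0) - EI**2

    from scipy.stats import norm

    z_n = (I - EI) / np.sqrt(var_n)
    z_r = (I - EI) / np.sqrt(var_r)
    return MoranResult(
        I=I,
        expected=EI,
        z_norm=float(z_n),
        p_norm=float(2 * norm.sf(abs(z_n))),
        z_rand=float(z_r),
        p_rand=float(2 * norm.sf(abs(z_r))),
        n=n,
        s0=float(s0),
    )


def moran_permutation_test(
    x: pd.Series,
    W: ContiguityWeights,
    nperm: int = 999,
    seed: int | None = None,
    *,
    two_sided: bool = False,
) -> tuple[float, float]:
    """Permutation test for global Moran's I.

    Values are randomly reassigned to units ``nperm`` times; the pseudo
    p-value is (1 + #{I_perm at least as extreme as I_obs}) / (1 + nperm),
    one-sided in the direction of the observed statistic by default.
    Returns (pseudo_p, permutation z-score).
    """
    if nperm < 99:
        raise ValueError("nperm must be at least 99")
    v, Wm, _ = _aligned(x, W)
    z = v - v.mean()
    I_obs = _moran_stat(z, Wm)
    rng = np.random.default_rng(seed)
    sims = np.empty(nperm)
    for k in range(nperm):
        sims[k] = _moran_stat(rng.permutation(z), Wm)
    if two_sided:
        center = sims.mean()
        extreme = np.abs(sims - center) >= abs(I_obs - center)
    elif I_obs >= -1.0 / (z.size - 1):
        extreme = sims >= I_obs
    else:
        extreme = sims <= I_obs
    p = (1 + int(extreme.sum())) / (1 + nperm)
    z_perm = (I_obs - sims.mean()) / sims.std(ddof=1)
    return float(p), float(z_perm)


def local_moran(
    x: pd.Series,
    W: ContiguityWeights,
    nperm: int = 999,
    alpha: float = 0.05,
    bonferroni: bool = False,
    seed: int | None = None,
    *,
    scale: str = "deviation",
) -> pd.DataFrame:
    """Local Moran's I (LISA) with conditional-permutation pseudo p-values.

    For each non-island unit i, I_i = (z_i / m2) * sum_j w_ij z_j with
    z the mean deviations and m2 = sum z^2 / n. The conditional permutation
    holds z_i fixed and draws its neighbors' values from the remaining
    units; the one-sided (in the direction of I_i) pseudo p is
    (1 + #extreme) / (1 + nperm). Quadrants: HH/LL/HL/LH from the sign of
    z_i and of its spatial lag. ``bonferroni_significant`` applies alpha/n.

    ``scale="raw"`` evaluates the literal raw-value form x_i * sum w_ij x_j
    (quadrants still derive from mean deviations).

    Island units are emitted with NaN I_i and quadrant "island".
    """
    if scale not in ("deviation", "raw"):
        raise ValueError("scale must be 'deviation' or 'raw'")
    v, Wm, ids = _aligned(x, W)
    n = len(ids)
    rng = np.random.default_rng(seed)
    z = v - v.mean()
    m2 = (z @ z) / n
    lag_z = Wm @ z
    if scale == "deviation":
        Ii = z / m2 * lag_z
    else:
        Ii = v * (Wm @ v)

    quad = np.where(
        z >= 0,
        np.where(lag_z >= 0, "HH", "HL"),
        np.where(lag_z >= 0, "LH", "LL"),
    )

    # conditional permutation: a shared pool of permutations of n-1 indices,
    # mapped per unit onto "all units except i"
    k_max = max(int((Wm[i] != 0).sum()) for i in range(n))
    pool = np.argsort(rng.random((nperm, n - 1)), axis=1)[:, :k_max]
    pseudo_p = np.empty(n)
    base = z if scale == "deviation" else v
    for i in range(n):
        nbr_idx = np.flatnonzero(Wm[i])
        k = nbr_idx.size
        others = np.delete(np.arange(n), i)
        wts = Wm[i, nbr_idx]
        draws = base[others[pool[:, :k]]]  # (nperm, k)
        lag_sim = draws @ wts
        if scale == "deviation":
            Ii_sim = z[i] / m2 * lag_sim
        else:
            Ii_sim = v[i] * lag_sim
        if Ii[i] >= Ii_sim.mean():
            extreme = Ii_sim >= Ii[i]
        else:
            extreme = Ii_sim <= Ii[i]
        pseudo_p[i] = (1 + int(extreme.sum())) / (1 + nperm)

    out = pd.DataFrame(
        {
            "unit_id": ids,
            "Ii": Ii,
            "quadrant": quad,
            "pseudo_p": pseudo_p,
            "significant": pseudo_p <= alpha,
            "bonferroni_significant": pseudo_p <= alpha / n,
        }
    )
    islands = [i for i in W.islands if i in x.index]
    if islands:
        pad = pd.DataFrame(
            {
                "unit_id": islands,
                "Ii": np.nan,
                "quadrant": "island",
                "pseudo_p": np.nan,
                "significant": False,
                "bonferroni_significant": False,
            }
        )
        out = pd.concat([out, pad], ignore_index=True)
    if bonferroni:
        out["significant"] = out["bonferroni_significant"]
    return out


def moran_scatter_data(x: pd.Series, W: ContiguityWeights) -> pd.DataFrame:
    """Mean deviation and its spatial lag per unit, for Moran scatterplots."""
    v, Wm, ids = _aligned(x, W)
    z = v - v.mean()
    return pd.DataFrame({"unit_id": ids, "z": z, "lag_z": Wm @ z})
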