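"""Environment-community association: Mantel tests, geographic distances,
and distance-decay regressions of community dissimilarity on per-factor
differences.

Environmental distance is the absolute pairwise difference of one factor at
a time (one matrix per factor); a combined z-scored Euclidean option exists
for multi-factor distance. Significance of the decay regressions uses
Mantel-style permutation because pairwise dissimilarities are not
independent observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics.pairwise import haversine_distances

from .beta import DistanceMatrix, euclidean_1d
from .tables import EnvTable, ValidationError

__all__ = [
    "MantelResult",
    "DecayFit",
    "mantel",
    "mantel_panel",
    "geo_distance",
    "env_distance",
    "distance_decay",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class MantelResult:
    factor: str
    r: float
    p: float
    n_perm: int
    method: str


@dataclass
class DecayFit:
    predictor: str
    slope: float
    intercept: float
    r: float
    p: float
    defined: bool = True


def _rank_square(d: np.ndarray) -> np.ndarray:
    """Rank-transform the off-diagonal entries of a symmetric matrix in place
    of their values (ties averaged), keeping the square layout so sample
    permutations still permute entries consistently."""
    iu = np.triu_indices(d.shape[0], 1)
    ranks = stats.rankdata(d[iu])
    out = np.zeros_like(d, dtype=float)
    out[iu] = ranks
    return out + out.T


def mantel(
    d_community: DistanceMatrix,
    d_env: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    method: str = "pearson",
    factor: str = "",
) -> MantelResult:
    """Mantel test: correlation of two distance matrices' off-diagonal
    entries, one-sided p from joint row/column permutation of one matrix.

    p = (1 + #{r_perm >= r_obs}) / (1 + n_perm).
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown method {method!r}")
    if n_perm < 99:
        raise ValidationError("need >= 99 permutations")
    x_cond, y_cond = d_community.align(d_env)
    n = d_community.n
    order = [d_env.ids.index(i) for i in d_community.ids]
    y_sq = d_env.values[np.ix_(order, order)]
    x_sq = d_community.values
    if method == "spearman":
        x_sq, y_sq = _rank_square(x_sq), _rank_square(y_sq)
    iu = np.triu_indices(n, 1)
    x = x_sq[iu]
    x = (x - x.mean()) / x.std()
    y0 = y_sq[iu]

    def corr(yv):
        sd = yv.std()
        if sd == 0:
            return 0.0
        return float((x * (yv - yv.mean())).mean() / sd)

    r_obs = corr(y0)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        hits += corr(y_sq[np.ix_(idx, idx)][iu]) >= r_obs
    return MantelResult(
        factor=factor,
        r=r_obs,
        p=(1 + hits) / (1 + n_perm),
        n_perm=n_perm,
        method=method,
    )


def env_distance(
    env: EnvTable, factor: str | list[str], samples: list[str] | None = None
) -> DistanceMatrix:
    """Per-factor absolute-difference distance, or combined z-scored
    Euclidean distance when a list of factors is given. Samples with a
    missing value for a requested factor are excluded."""
    df = env.factors if samples is None else env.factors.loc[samples]
    if isinstance(factor, str):
        col = df[factor].dropna()
        return euclidean_1d(list(col.index), col.to_numpy(), metric=f"|d{factor}|")
    sub = df[list(factor)].dropna()
    z = (sub - sub.mean()) / sub.std(ddof=0)
    return DistanceMatrix(
        list(sub.index), squareform(pdist(z.to_numpy())), metric="env-euclidean-z"
    )


def mantel_panel(
    d_community: DistanceMatrix,
    env: EnvTable,
    factors: list[str],
    n_perm: int = 999,
    seed: int = 0,
    method: str = "pearson",
) -> pd.DataFrame:
    """One Mantel test per environmental factor against the community matrix,
    restricted to samples with a value for that factor."""
    rows = []
    for i, f in enumerate(factors):
        d_env = env_distance(env, f)
        common = [s for s in d_community.ids if s in d_env.ids]
        idx = [d_community.ids.index(s) for s in common]
        d_comm_sub = DistanceMatrix(
            common, d_community.values[np.ix_(idx, idx)], d_community.metric
        )
        jdx = [d_env.ids.index(s) for s in common]
        d_env_sub = DistanceMatrix(common, d_env.values[np.ix_(jdx, jdx)], d_env.metric)
        res = mantel(
            d_comm_sub, d_env_sub, n_perm=n_perm, seed=seed + i, method=method, factor=f
        )
        rows.append(
            {"factor": f, "r": res.r, "p": res.p, "n": len(common), "n_perm": n_perm}
        )
    return pd.DataFrame(rows)


def geo_distance(metadata: pd.DataFrame) -> DistanceMatrix:
    """Great-circle (haversine) distances in km from decimal-degree
    latitude/longitude metadata columns, Earth radius 6371 km."""
    for col in ("latitude", "longitude"):
        if col not in metadata.columns:
            raise ValidationError(f"metadata lacks {col!r}")
        if metadata[col].isna().any():
            bad = metadata.index[metadata[col].isna()].tolist()
            raise ValidationError(f"missing coordinates for samples: {bad}")
    pts = np.radians(metadata[["latitude", "longitude"]].to_numpy(dtype=float))
    d = haversine_distances(pts) * EARTH_RADIUS_KM
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(metadata.index), d, metric="great-circle-km")


def distance_decay(
    d_community: DistanceMatrix,
    d_predictor: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    predictor: str = "",
) -> DecayFit:
    """OLS of community dissimilarity on a pairwise predictor difference,
    with permutation significance (two-sided on r) honouring the pair
    structure of the dissimilarities."""
    y, x = d_community.align(d_predictor)
    if np.allclose(x.std(), 0):
        return DecayFit(
            predictor=predictor, slope=float("nan"), intercept=float("nan"),
            r=float("nan"), p=float("nan"), defined=False,
        )
    fit = stats.linregress(x, y)
    n = d_community.n
    order = [d_predictor.ids.index(i) for i in d_community.ids]
    x_sq = d_predictor.values[np.ix_(order, order)]
    iu = np.triu_indices(n, 1)
    yc = (y - y.mean()) / y.std()
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        xv = x_sq[np.ix_(idx, idx)][iu]
        sd = xv.std()
        r_perm = 0.0 if sd == 0 else (yc * (xv - xv.mean())).mean() / sd
        hits += abs(r_perm) >= abs(fit.rvalue)
    return DecayFit(
        predictor=predictor,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p=(1 + hits) / (1 + n_perm),
    )
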