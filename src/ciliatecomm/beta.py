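"""Beta diversity: Bray-Curtis dissimilarity, non-metric multidimensional
scaling (NMDS, Kruskal stress-1), and PERMANOVA group-separation tests."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from .tables import AbundanceTable, ValidationError

__all__ = ["DistanceMatrix", "bray_curtis", "euclidean_1d", "nmds", "permanova", "Ordination"]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix over labelled samples."""

    ids: list[str]
    values: np.ndarray
    metric: str = "bray-curtis"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal is not zero")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def align(self, other: "DistanceMatrix") -> tuple[np.ndarray, np.ndarray]:
        """Return both condensed vectors over the shared (identical) id set."""
        if set(self.ids) != set(other.ids):
            diff = set(self.ids) ^ set(other.ids)
            raise ValidationError(f"sample sets differ: {sorted(diff)}")
        order = [other.ids.index(i) for i in self.ids]
        reordered = other.values[np.ix_(order, order)]
        return self.condensed(), squareform(reordered, checks=False)


def bray_curtis(ab: AbundanceTable, relativize: bool = False) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(x,y) = sum|x_i - y_i| / sum(x_i + y_i).

    Raw counts by default; ``relativize=True`` converts to per-sample
    relative abundances first.
    """
    totals = ab.sample_totals
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValidationError(f"zero-total samples: {bad}")
    X = ab.relativize().to_numpy() if relativize else ab.counts.to_numpy(dtype=float)
    d = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(ab.samples, d, metric="bray-curtis")


def euclidean_1d(ids: list[str], values, metric: str = "euclidean") -> DistanceMatrix:
    """Pairwise absolute differences of a single variable (e.g. one soil factor)."""
    v = np.asarray(values, dtype=float).reshape(-1, 1)
    return DistanceMatrix(list(ids), squareform(pdist(v)), metric=metric)


@dataclass
class Ordination:
    coordinates: pd.DataFrame
    stress: float
    k: int
    converged: bool
    seed: int
    restarts: int = field(default=50)


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    restarts: int = 50,
    seed: int = 0,
    max_iter: int = 500,
) -> Ordination:
    """Non-metric MDS of a distance matrix; lowest Kruskal stress-1 over
    random restarts, deterministic under the seed."""
    if k < 2:
        raise ValidationError("k must be >= 2")
    if d.n <= k + 1:
        raise ValidationError(f"need more than k+1={k + 1} samples, got {d.n}")
    model = MDS(
        n_components=k,
        metric_mds=False,
        n_init=restarts,
        init="random",
        max_iter=max_iter,
        metric="precomputed",
        random_state=seed,
        normalized_stress=True,
        eps=1e-9,
    )
    coords = model.fit_transform(d.values)
    converged = bool(model.n_iter_ < max_iter)
    return Ordination(
        coordinates=pd.DataFrame(
            coords, index=d.ids, columns=[f"NMDS{i + 1}" for i in range(k)]
        ),
        stress=float(model.stress_),
        k=k,
        converged=converged,
        seed=seed,
        restarts=restarts,
    )


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """PERMANOVA pseudo-F from a squared-distance matrix and group codes."""
    n = d2.shape[0]
    sst = d2[np.triu_indices(n, 1)].sum() / n
    ssw = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ssw += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ssa = sst - ssw
    dfa, dfw = n_groups - 1, n - n_groups
    if ssw <= 0:
        return np.inf if ssa > 0 else 0.0
    return (ssa / dfa) / (ssw / dfw)


def permanova(
    d: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Permutational multivariate ANOVA on a distance matrix.

    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm), labels permuted whole.
    """
    groups = np.asarray(groups)
    if len(groups) != d.n:
        raise ValidationError("group labels do not match distance matrix")
    labels, codes = np.unique(groups, return_inverse=True)
    if len(labels) < 2:
        raise ValidationError("all samples in one group")
    if n_perm < 99:
        raise ValidationError("need >= 99 permutations")
    d2 = d.values**2
    f_obs = _pseudo_f(d2, codes, len(labels))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        hits += _pseudo_f(d2, rng.permutation(codes), len(labels)) >= f_obs
    return {
        "pseudo_F": float(f_obs),
        "p": (1 + hits) / (1 + n_perm),
        "n_perm": n_perm,
        "groups": labels.tolist(),
    }
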