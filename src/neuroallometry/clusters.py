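"""Pairwise scaling slopes and hierarchical clustering of neuropils.

Neuropils that scale together across the phylogeny plausibly form
functional units.  To find them, every neuropil's log relative volume
is PGLS-regressed on every other's, the asymmetric slope matrix is
symmetrized into a signed association, the association is turned into a
distance (d = 1 - association, so proportional scaling gives d near 0
and strong negative coupling d near 2), and the distance matrix is
clustered agglomeratively.  The raw asymmetric slope matrix is kept so
alternative transforms can be applied downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .allometry import pgls_fit
from .tree import PhyloCovariance

__all__ = [
    "SlopeMatrix",
    "ClusterResult",
    "pairwise_slopes",
    "to_distance",
    "hcluster",
    "linkage_to_newick",
]


@dataclass
class SlopeMatrix:
    """All ordered-pair PGLS slopes among neuropils.

    ``slopes.loc[i, j]`` is the slope of regressing log relative volume
    of neuropil i on neuropil j; the diagonal is 1 by definition.
    ``se`` and ``r2_adj`` are companion matrices; cells with too little
    species overlap are NaN.
    """

    slopes: pd.DataFrame
    se: pd.DataFrame
    r2_adj: pd.DataFrame

    @property
    def neuropils(self) -> list[str]:
        return list(self.slopes.index)


def pairwise_slopes(
    log_traits: pd.DataFrame,
    C: PhyloCovariance,
    min_species: int = 4,
) -> SlopeMatrix:
    """PGLS slope for every ordered neuropil pair.

    ``log_traits`` is a species x neuropil matrix of log relative
    volumes (missing entries allowed).  Pairs whose shared species
    count falls below ``min_species`` are left missing.
    """
    cols = list(log_traits.columns)
    if len(cols) < 3:
        raise ValueError("need at least 3 neuropils")
    k = len(cols)
    B = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    SE = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    R2 = pd.DataFrame(np.ones((k, k)), index=cols, columns=cols)
    for i in cols:
        for j in cols:
            if i == j:
                continue
            sub = log_traits[[i, j]].dropna()
            if len(sub) < min_species:
                B.loc[i, j] = SE.loc[i, j] = R2.loc[i, j] = np.nan
                continue
            y = sub[i]
            X = pd.DataFrame({"intercept": 1.0, "log_x": sub[j]})
            fit = pgls_fit(y, X, C)
            B.loc[i, j] = fit.params["log_x"]
            SE.loc[i, j] = fit.se["log_x"]
            R2.loc[i, j] = fit.r2_adj
    return SlopeMatrix(slopes=B, se=SE, r2_adj=R2)


def to_distance(sm: SlopeMatrix, strict: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetrize slopes into a signed association and a distance matrix.

    The association of a pair is the mean of its two directed slopes,
    normalized by the largest absolute off-diagonal association so that
    values lie in [-1, 1]; the distance is 1 - association (0 for
    perfectly synchronous scaling, 2 for maximal negative coupling).
    Missing cells are imputed with the row/column median of the
    association matrix (with a warning), or rejected in strict mode.

    Returns ``(association, distance)``.
    """
    B = sm.slopes.to_numpy(dtype=float)
    S = (B + B.T) / 2.0
    np.fill_diagonal(S, np.nan)
    off = ~np.eye(S.shape[0], dtype=bool)
    missing = np.isnan(S) & off
    if (missing | ~off).all(axis=1).any():
        bad = [sm.neuropils[i]
               for i in np.flatnonzero((missing | ~off).all(axis=1))]
        raise ValueError(f"neuropils with no valid pair: {bad}")
    if missing.any():
        if strict:
            raise ValueError("slope matrix has missing cells (strict mode)")
        warnings.warn("imputing missing association cells with row/column medians",
                      stacklevel=2)
        med = np.nanmedian(S, axis=1)
        for i, j in zip(*np.where(missing)):
            S[i, j] = S[j, i] = (med[i] + med[j]) / 2.0
    scale = np.nanmax(np.abs(S))
    if scale > 0:
        S = S / scale
    np.fill_diagonal(S, 1.0)
    D = 1.0 - S
    np.fill_diagonal(D, 0.0)
    idx = sm.neuropils
    return (pd.DataFrame(S, index=idx, columns=idx),
            pd.DataFrame(D, index=idx, columns=idx))


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: list[str]
    method: str

    def flat(self, k: int | None = None, height: float | None = None) -> pd.Series:
        """Flat cluster assignments by cluster count or cut height."""
        if (k is None) == (height is None):
            raise ValueError("give exactly one of k or height")
        if k is not None:
            assign = hierarchy.fcluster(self.linkage, k, criterion="maxclust")
        else:
            assign = hierarchy.fcluster(self.linkage, height, criterion="distance")
        return pd.Series(assign, index=self.labels, name="cluster")

    def to_newick(self) -> str:
        return linkage_to_newick(self.linkage, self.labels)


def hcluster(distance: pd.DataFrame, method: str = "average") -> ClusterResult:
    """Agglomerative clustering of a neuropil distance matrix."""
    D = distance.to_numpy(dtype=float)
    if not np.isfinite(D).all():
        raise ValueError("distance matrix contains non-finite values")
    if not np.allclose(D, D.T) or np.abs(np.diag(D)).max() > 1e-12:
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if D.shape[0] == 1:
        return ClusterResult(np.empty((0, 4)), list(distance.index), method)
    Z = hierarchy.linkage(squareform(D, checks=False), method=method)
    return ClusterResult(Z, list(distance.index), method)


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a SciPy linkage matrix as a Newick string.

    Branch lengths are differences in merge height, so the tree is
    ultrametric with tip depth equal to the final merge height.
    """
    n = len(labels)
    if n == 1:
        return f"{labels[0]}:0.0;"

    def height(node: int) -> float:
        return 0.0 if node < n else Z[node - n, 2]

    def render(node: int, parent_h: float) -> str:
        bl = parent_h - height(node)
        if node < n:
            return f"{labels[node]}:{bl:.10g}"
        left, right = int(Z[node - n, 0]), int(Z[node - n, 1])
        h = height(node)
        return f"({render(left, h)},{render(right, h)}):{bl:.10g}"

    root = n + Z.shape[0] - 1
    h = height(root)
    left, right = int(Z[-1, 0]), int(Z[-1, 1])
    return f"({render(left, h)},{render(right, h)});"
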