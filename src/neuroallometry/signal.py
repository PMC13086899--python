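"""Blomberg's K and its two hypothesis tests.

K measures how strongly a continuous trait tracks the phylogeny.  It is
the ratio of the observed mean squared error of tip values around the
phylogenetically weighted mean (ignoring the tree) to the mean squared
error under the tree's covariance structure, scaled by the expectation
of that ratio under Brownian motion, so that K = 1 means "exactly the
similarity among relatives that Brownian motion predicts", K < 1 less,
K > 1 more.

With covariance matrix C, trait vector x of length n and the
phylogenetic mean  a = (1'C^-1 1)^-1 1'C^-1 x :

    MSE0 = (x - a)'(x - a) / (n - 1)
    MSE  = (x - a)' C^-1 (x - a) / (n - 1)
    K    = (MSE0 / MSE) / [(tr C - n / (1'C^-1 1)) / (n - 1)]

Two tests accompany the point estimate: a one-sided permutation test of
K = 0 (shuffling tip values across the phylogeny destroys any signal)
and a two-sided test of K = 1 against the distribution of K in traits
simulated under Brownian motion on the same tree.  Both use the add-one
convention p = (1 + #exceedances) / (n_draws + 1), so p is never 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .simulate import simulate_bm
from .tree import PhyloCovariance, PhyloTree

__all__ = [
    "SignalResult",
    "blomberg_k",
    "permutation_test_k0",
    "bm_simulation_test_k1",
    "signal_test",
    "signal_table",
]


@dataclass
class SignalResult:
    trait: str
    k: float
    p_k0: float
    p_k1: float
    n_permutations: int
    n_simulations: int
    seed: int | None


class _KEngine:
    """Precomputed tree quantities for evaluating K on many trait vectors."""

    def __init__(self, C: np.ndarray):
        n = C.shape[0]
        if n < 3:
            raise ValueError("K requires at least 3 species")
        try:
            self._cho = cho_factor(C)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "phylogenetic covariance matrix is singular; check for "
                "duplicated tips with zero divergence"
            ) from exc
        one = np.ones(n)
        self._w = cho_solve(self._cho, one)  # C^-1 1
        self._denom = one @ self._w          # 1'C^-1 1
        self._n = n
        self.expected_ratio = (np.trace(C) - n / self._denom) / (n - 1)

    def k(self, X: np.ndarray) -> np.ndarray:
        """K for each row of a (m, n) trait matrix (or a single vector)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if np.ptp(X, axis=1).min() == 0:
            raise ValueError("constant trait: K is undefined")
        a = (X @ self._w) / self._denom
        d = X - a[:, None]
        mse0 = np.einsum("ij,ij->i", d, d)
        mse = np.einsum("ij,ij->i", d, cho_solve(self._cho, d.T).T)
        return (mse0 / mse) / self.expected_ratio


def _as_cov(tree: PhyloTree | PhyloCovariance) -> PhyloCovariance:
    return tree.vcv() if isinstance(tree, PhyloTree) else tree


def _align(cov: PhyloCovariance, trait) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(trait, pd.Series):
        missing = [s for s in cov.species if s not in trait.index]
        if missing:
            raise ValueError(f"trait missing for species: {missing}")
        x = trait.reindex(cov.species).to_numpy(dtype=float)
    else:
        x = np.asarray(trait, dtype=float)
        if x.shape != (len(cov.species),):
            raise ValueError("trait length does not match number of tips")
    if not np.isfinite(x).all():
        raise ValueError("trait contains non-finite values")
    return x, cov.matrix


def blomberg_k(tree: PhyloTree | PhyloCovariance, trait) -> float:
    """Blomberg's K for one trait (tip-ordered array or species-indexed Series)."""
    cov = _as_cov(tree)
    x, C = _align(cov, trait)
    return float(_KEngine(C).k(x)[0])


def permutation_test_k0(
    tree: PhyloTree | PhyloCovariance,
    trait,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """One-sided permutation p-value for "no phylogenetic signal" (K = 0).

    Tip values are shuffled across the phylogeny ``n_perm`` times;
    large observed K relative to the shuffled K distribution is
    evidence of signal.
    """
    cov = _as_cov(tree)
    x, C = _align(cov, trait)
    eng = _KEngine(C)
    k_obs = eng.k(x)[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perms = rng.permuted(np.broadcast_to(x, (n_perm, x.size)).copy(), axis=1)
    k_perm = eng.k(perms)
    return float((1 + np.sum(k_perm >= k_obs)) / (n_perm + 1))


def bm_simulation_test_k1(
    tree: PhyloTree,
    trait,
    n_sim: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Two-sided p-value for "K as expected under Brownian motion" (K = 1).

    K is computed for ``n_sim`` traits simulated under Brownian motion
    on the tree (unit rate; K is scale-invariant), and the observed K is
    ranked within that null distribution from both sides.
    """
    if not isinstance(tree, PhyloTree):
        raise TypeError("bm_simulation_test_k1 needs the tree itself, not only C")
    cov = tree.vcv()
    x, C = _align(cov, trait)
    eng = _KEngine(C)
    k_obs = eng.k(x)[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sims = simulate_bm(tree, 1.0, 0.0, rng, size=n_sim)
    k_sim = eng.k(sims)
    lo = (1 + np.sum(k_sim <= k_obs)) / (n_sim + 1)
    hi = (1 + np.sum(k_sim >= k_obs)) / (n_sim + 1)
    return float(min(1.0, 2.0 * min(lo, hi)))


def signal_test(
    tree: PhyloTree,
    trait,
    label: str = "",
    n_perm: int = 10_000,
    n_sim: int = 10_000,
    seed: int = 0,
) -> SignalResult:
    """K plus both hypothesis tests for one trait."""
    ss = np.random.SeedSequence(seed)
    s_perm, s_sim = ss.spawn(2)
    cov = tree.vcv()
    return SignalResult(
        trait=label,
        k=blomberg_k(cov, trait),
        p_k0=permutation_test_k0(cov, trait, n_perm, np.random.default_rng(s_perm)),
        p_k1=bm_simulation_test_k1(tree, trait, n_sim, np.random.default_rng(s_sim)),
        n_permutations=n_perm,
        n_simulations=n_sim,
        seed=seed,
    )


def signal_table(
    tree: PhyloTree,
    traits: pd.DataFrame,
    n_perm: int = 10_000,
    n_sim: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-trait K with both tests, for a species x trait DataFrame.

    Traits are typically log10 relative neuropil volumes.  Species with
    a missing value are dropped per trait (the tree is pruned
    accordingly); each trait gets its own deterministic random stream
    derived from ``seed``.
    """
    rows = []
    streams = np.random.SeedSequence(seed).spawn(traits.shape[1])
    for stream, col in zip(streams, traits.columns):
        x = traits[col].dropna()
        sub = tree if len(x) == len(tree.tip_labels) else tree.prune_to(list(x.index))
        res = signal_test(sub, x, label=col, n_perm=n_perm, n_sim=n_sim,
                          seed=int(stream.generate_state(1)[0] % (2**31)))
        rows.append(
            {
                "neuropil": col,
                "n": len(x),
                "K": res.k,
                "p_K0": res.p_k0,
                "p_K1": res.p_k1,
                "K_ne_0": res.p_k0 < alpha,
                "K_ne_1": res.p_k1 < alpha,
            }
        )
    return pd.DataFrame(rows).set_index("neuropil")
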