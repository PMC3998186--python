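"""Concordance between genetic distances and metabolite-level differences.

Formalizes "do genetically close samples have similar verbascoside levels?"
as a one-sided Mantel test: Pearson correlation between the upper triangles
of the two distance matrices, with significance from permuting the sample
labels of the second matrix.  Exact enumeration of all label permutations is
used automatically for small sample sets.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from chemotax.distance_clustering import DistanceMatrix

__all__ = ["ConcordanceResult", "concentration_difference_matrix", "mantel"]

# n! permutations are enumerated exhaustively up to this many samples (7! = 5040)
EXACT_ENUMERATION_MAX_N = 7


@dataclass(frozen=True)
class ConcordanceResult:
    """Mantel correlation with one-sided permutation p-value."""

    r: float
    p: float
    n_perm: int
    seed: int | None
    exact: bool

    def to_json_line(self) -> str:
        return (
            f'{{"r": {self.r:.6f}, "p": {self.p:.6g}, "n_perm": {self.n_perm}, '
            f'"seed": {self.seed if self.seed is not None else "null"}, '
            f'"exact": {str(self.exact).lower()}}}'
        )


def concentration_difference_matrix(quant: pd.DataFrame) -> DistanceMatrix:
    """Pairwise absolute concentration differences, rescaled to [0, 1].

    Parameters
    ----------
    quant
        Frame indexed by sample with a ``mean_concentration`` column (the
        output of :func:`chemotax.densitometry.quantify`).

    The entry (i, j) is ``|mean_i - mean_j|`` divided by the maximum pairwise
    difference; if all means are equal the unscaled zero matrix is returned
    with a warning.
    """
    if len(quant) < 2:
        raise ValueError("need at least 2 samples")
    means = quant["mean_concentration"].to_numpy(dtype=float)
    diff = np.abs(means[:, None] - means[None, :])
    max_diff = diff.max()
    if max_diff == 0:
        warnings.warn("all mean concentrations are equal; returning zero matrix")
        return DistanceMatrix(tuple(quant.index), diff)
    return DistanceMatrix(tuple(quant.index), diff / max_diff)


def _triu(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> ConcordanceResult:
    """One-sided Mantel test for positive association between two matrices.

    r is the Pearson correlation over the strict upper triangles.  The null
    distribution permutes the sample labels of ``d2``;
    ``p = (1 + #{r_perm >= r_obs}) / (n_perm + 1)`` for Monte-Carlo sampling,
    or the exact fraction of all n! relabelings when n <= 7.

    ``d2`` may list the same samples in a different order; it is aligned to
    ``d1`` first.
    """
    if set(d1.ids) != set(d2.ids):
        raise ValueError("matrices are over different sample sets")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    order = [d2.ids.index(s) for s in d1.ids]
    m2 = d2.values[np.ix_(order, order)]
    x = _triu(d1.values)
    n = d1.n

    def corr_with(perm: np.ndarray) -> float:
        return float(np.corrcoef(x, _triu(m2[np.ix_(perm, perm)]))[0, 1])

    if np.ptp(x) == 0 or np.ptp(_triu(m2)) == 0:
        raise ValueError("constant distance triangle; correlation undefined")
    r_obs = corr_with(np.arange(n))

    if n <= EXACT_ENUMERATION_MAX_N:
        perms = itertools.permutations(range(n))
        count = sum(corr_with(np.array(p)) >= r_obs - 1e-12 for p in perms)
        total = math.factorial(n)
        return ConcordanceResult(r_obs, count / total, total, seed, exact=True)

    rng = np.random.default_rng(seed)
    # vectorized: permute rows/cols of m2 for all draws at once
    perms = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
    iu = np.triu_indices(n, k=1)
    permuted = m2[perms[:, :, None], perms[:, None, :]][:, iu[0], iu[1]]
    xc = x - x.mean()
    pc = permuted - permuted.mean(axis=1, keepdims=True)
    r_perm = (pc @ xc) / (
        np.sqrt((pc**2).sum(axis=1)) * np.sqrt((xc**2).sum())
    )
    count = int(np.sum(r_perm >= r_obs - 1e-12))
    p = (1 + count) / (n_perm + 1)
    return ConcordanceResult(r_obs, p, n_perm, seed, exact=False)
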