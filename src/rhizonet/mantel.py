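"""Mantel tests between community dissimilarity and environmental distance.

Community distance defaults to Bray-Curtis on the abundance table;
environmental distance to Euclidean distance on z-scored variables.  The
Mantel statistic is the Pearson correlation of the two matrices' upper
triangles, with significance from simultaneous row/column permutations of
one matrix under the one-sided positive alternative (the convention in
microbial ecology, where the question is whether environmentally closer
samples host more similar communities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .abundance import AbundanceTable


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        if (v < 0).any():
            raise ValueError("distances must be nonnegative")


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples: sum|x-y| / sum(x+y)."""
    x = table.values.to_numpy(dtype=float).T  # samples x OTUs
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    zero = x.sum(axis=1) == 0
    if zero.sum() >= 2:
        bad = [s for s, z in zip(table.sample_ids, zero) if z]
        raise ValueError(f"Bray-Curtis undefined between all-zero samples: {bad}")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(sample_ids=table.sample_ids, values=d, metric="braycurtis")


def euclidean_env(env: pd.DataFrame, standardize: bool = True) -> DistanceMatrix:
    """Euclidean distance between samples on (optionally z-scored) variables.

    Constant variables carry no distance information when standardizing and
    are dropped with a warning.
    """
    values = env.to_numpy(dtype=float)
    if standardize:
        sd = values.std(axis=0, ddof=1)
        constant = sd == 0
        if constant.any():
            dropped = env.columns[constant].tolist()
            warnings.warn(f"dropping constant environmental variables: {dropped}")
            values = values[:, ~constant]
            sd = sd[~constant]
        values = (values - values.mean(axis=0)) / sd
    d = squareform(pdist(values, metric="euclidean"))
    return DistanceMatrix(sample_ids=env.index.tolist(), values=d, metric="euclidean")


def mantel(
    d_a: DistanceMatrix,
    d_b: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel correlation and one-sided permutation p-value.

    r is the Pearson correlation of the upper-triangle entries; the null
    distribution permutes the rows and columns of the second matrix
    simultaneously, and p = (1 + #{perm r >= observed}) / (1 + n_perm), so
    the smallest attainable p is 1/(n_perm + 1).
    """
    if d_a.sample_ids != d_b.sample_ids:
        diff = sorted(set(d_a.sample_ids) ^ set(d_b.sample_ids))
        raise ValueError(f"sample sets differ: {diff or 'ordering mismatch'}")
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    n = len(d_a.sample_ids)
    iu = np.triu_indices(n, k=1)
    a = d_a.values[iu]
    rng = np.random.default_rng(seed)

    def corr_with(b_matrix: np.ndarray) -> float:
        b = b_matrix[iu]
        return float(np.corrcoef(a, b)[0, 1])

    observed = corr_with(d_b.values)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr_with(d_b.values[np.ix_(perm, perm)]) >= observed:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return observed, float(p)
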