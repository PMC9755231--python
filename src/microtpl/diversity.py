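"""Supporting community statistics: Shannon diversity, Kruskal-Wallis,
Bray-Curtis dissimilarity and the ANOSIM permutation test.

Shannon entropy uses the natural log (nats).  ANOSIM is implemented here
directly (rank-based R statistic with midranks for ties and an add-one
permutation p-value) so the permutation stream is seedable and, on small
problems, exhaustively enumerable.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform

from .io_formats import OtuTable

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with sample labels."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0):
            raise ValueError("distance matrix diagonal is not zero")
        self.d = d

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


@dataclass(frozen=True)
class AnosimResult:
    R: float
    p_value: float
    n_permutations: int
    seed: Optional[int]


def shannon(counts: Sequence[float]) -> float:
    """Shannon index H = -sum p_k ln p_k over positive proportions (nats)."""
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("negative counts")
    total = x.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero sample")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def shannon_per_sample(table: OtuTable) -> pd.Series:
    values = {sid: shannon(table.counts[sid].to_numpy()) for sid in table.sample_ids}
    return pd.Series(values, name="shannon")


def kruskal_wallis(values: Sequence[float], groups: Sequence[str]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) across labeled groups.

    Returns (H, p) with p from the chi-squared distribution on k-1 df.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    if len(values) != len(labels):
        raise ValueError("values and groups differ in length")
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    samples = [values[labels == g] for g in uniq]
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    if np.ptp(values) == 0:
        # every value identical: no rank separation at all
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples.

    d(i, j) = sum_k |x_ki - x_kj| / sum_k (x_ki + x_kj).  A pair of all-zero
    samples has an undefined quotient; it is defined as 0 here (identical
    emptiness) with a warning.
    """
    if table.n_samples < 2:
        raise ValueError("need >= 2 samples for a distance matrix")
    X = table.counts.to_numpy().T  # samples x OTUs
    n = X.shape[0]
    d = np.zeros((n, n))
    zero_pairs = 0
    for i in range(n - 1):
        diff = np.abs(X[i] - X[i + 1:]).sum(axis=1)
        tot = (X[i] + X[i + 1:]).sum(axis=1)
        empty = tot == 0
        zero_pairs += int(empty.sum())
        tot[empty] = 1.0
        row = diff / tot
        row[empty] = 0.0
        d[i, i + 1:] = row
        d[i + 1:, i] = row
    if zero_pairs:
        logger.warning(
            "bray_curtis: %d all-zero sample pair(s); distance defined as 0", zero_pairs
        )
    return DistanceMatrix(labels=list(table.sample_ids), d=d)


def _anosim_r(ranks: np.ndarray, within: np.ndarray, denom: float) -> float:
    return float((ranks[~within].mean() - ranks[within].mean()) / denom)


def anosim(
    d: DistanceMatrix,
    groups: Sequence[str],
    n_permutations: int = 999,
    seed: Optional[int] = None,
    exact: bool = False,
) -> AnosimResult:
    """Analysis of similarities: are between-group distances larger in rank
    than within-group distances?

    R = (mean rank between - mean rank within) / (N(N-1)/4), computed on the
    midranks of all pairwise distances; R is 1 when all between-group
    distances exceed all within-group ones and about 0 under no structure.
    The p-value permutes group labels with distances fixed and uses the
    add-one estimator p = (1 + #{R_perm >= R_obs}) / (1 + n_permutations),
    so p is never below 1/(n_permutations + 1).

    With ``exact=True`` all distinct label arrangements are enumerated
    instead (feasible for small N) and p is the exact permutation tail
    probability including the observed arrangement.
    """
    labels = np.asarray(groups)
    n = len(labels)
    if n != len(d.labels):
        raise ValueError("group labels do not match distance matrix size")
    if len(pd.unique(labels)) < 2:
        raise ValueError("ANOSIM needs >= 2 groups")
    iu, ju = np.triu_indices(n, k=1)
    ranks = stats.rankdata(d.condensed())  # midranks for ties
    denom = n * (n - 1) / 4.0
    within_obs = labels[iu] == labels[ju]
    if not within_obs.any():
        raise ValueError("ANOSIM needs at least one within-group pair (a group of size >= 2)")
    r_obs = _anosim_r(ranks, within_obs, denom)

    if exact:
        seen: set[tuple] = set()
        count_ge = 0
        total = 0
        for perm in itertools.permutations(labels):
            if perm in seen:
                continue
            seen.add(perm)
            lab = np.asarray(perm)
            total += 1
            if _anosim_r(ranks, lab[iu] == lab[ju], denom) >= r_obs - 1e-12:
                count_ge += 1
        return AnosimResult(R=r_obs, p_value=count_ge / total, n_permutations=total, seed=seed)

    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_permutations):
        lab = rng.permutation(labels)
        if _anosim_r(ranks, lab[iu] == lab[ju], denom) >= r_obs - 1e-12:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_permutations)
    return AnosimResult(R=r_obs, p_value=p, n_permutations=n_permutations, seed=seed)


def exhaustive_group_partitions(n: int, sizes: Sequence[int]) -> int:
    """Number of distinct label arrangements for given group sizes."""
    total = math.factorial(n)
    for s in sizes:
        total //= math.factorial(s)
    return total
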