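"""Principal coordinate analysis and permutation tests of group structure.

PCoA is classical metric scaling: Gower-center the squared distance matrix,
eigen-decompose, and scale eigenvectors by the square root of their (positive)
eigenvalues.  Negative eigenvalues — possible because the combined
Bruvo/Jaccard distance need not be Euclidean — are reported but excluded from
the coordinates and from the explained-variance denominator; an optional
Cailliez additive correction removes them entirely.

Group structure is probed with two one-sided permutation tests on the raw
distance matrix:

* between(g, h): statistic = mean cross-group distance, null = labels
  shuffled among the members of g ∪ h, large values significant (separation);
* within(g): statistic = mean within-group distance, null = random size-|g|
  subsets of all accessions, small values significant (compactness).

p-values use the add-one rule p = (1 + #{perm as or more extreme}) / (1 + N),
so the attainable minimum is 1/(N+1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .distance import DistanceMatrix
from .genotypes import GroupAssignment

__all__ = [
    "PCoAResult",
    "GroupDistanceTest",
    "pcoa",
    "group_mean_distances",
    "permutation_tests",
    "stars",
]


@dataclass(frozen=True)
class PCoAResult:
    ids: tuple[str, ...]
    coordinates: np.ndarray  # n x (number of positive axes)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    pct_variance: np.ndarray  # per positive axis, sums to 100

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def _gower_center(D2: np.ndarray) -> np.ndarray:
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ D2 @ J


def _cailliez_constant(D: np.ndarray) -> float:
    """Smallest additive constant making the matrix Euclidean (Cailliez)."""
    n = D.shape[0]
    d1 = _gower_center(D ** 2)
    d2 = _gower_center(D)
    Z = np.zeros((2 * n, 2 * n))
    Z[:n, n:] = 2.0 * d1
    Z[n:, :n] = -np.eye(n)
    Z[n:, n:] = -4.0 * d2
    ev = np.linalg.eigvals(Z)
    return float(max(ev.real.max(), 0.0))


def pcoa(D: DistanceMatrix, correction: Optional[str] = None) -> PCoAResult:
    """Classical scaling of a distance matrix.

    ``correction='cailliez'`` adds the Cailliez constant to all off-diagonal
    distances before decomposition (off by default).  Axis signs follow a
    fixed convention: the first nonzero loading of each axis is positive.
    """
    n = D.n
    if n < 3:
        raise ValueError("pcoa needs at least 3 accessions")
    M = D.values.copy()
    if correction == "cailliez":
        c = _cailliez_constant(M)
        M = M + c
        np.fill_diagonal(M, 0.0)
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    B = _gower_center(M ** 2)
    B = 0.5 * (B + B.T)
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-10
    pos = eigval > tol
    if not pos.any():
        # fully degenerate (all-zero) matrix: single zero axis
        return PCoAResult(
            ids=D.ids,
            coordinates=np.zeros((n, 1)),
            eigenvalues=eigval,
            pct_variance=np.array([0.0]),
        )
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    # sign convention: first nonzero loading of each axis positive
    for k in range(coords.shape[1]):
        col = coords[:, k]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, k] = -col
    pct = 100.0 * eigval[pos] / eigval[pos].sum()
    return PCoAResult(
        ids=D.ids, coordinates=coords, eigenvalues=eigval, pct_variance=pct
    )


def group_mean_distances(
    D: DistanceMatrix, groups: GroupAssignment
) -> tuple[tuple[str, ...], np.ndarray]:
    """G x G matrix of mean pairwise distances: diagonal = mean over unordered
    within-group pairs (NaN for singleton groups), off-diagonal = mean over
    all cross pairs."""
    labels = groups.groups
    pos = {a: i for i, a in enumerate(D.ids)}
    idx = {g: np.array([pos[a] for a in groups.members(g)]) for g in labels}
    G = len(labels)
    M = np.full((G, G), np.nan)
    for gi, g in enumerate(labels):
        ig = idx[g]
        if len(ig) >= 2:
            sub = D.values[np.ix_(ig, ig)]
            iu = np.triu_indices(len(ig), k=1)
            M[gi, gi] = sub[iu].mean()
        for hj in range(gi + 1, G):
            ih = idx[labels[hj]]
            M[gi, hj] = M[hj, gi] = D.values[np.ix_(ig, ih)].mean()
    return labels, M


def stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class GroupDistanceTest:
    group_a: str
    group_b: str  # equals group_a for the within-group compactness test
    mean_distance: float
    p_value: float
    n_permutations: int
    stars: str
    null_stats: Optional[np.ndarray] = None  # kept only on request

    @property
    def is_within(self) -> bool:
        return self.group_a == self.group_b

    @property
    def at_attainable_minimum(self) -> bool:
        """True when no permutation statistic was strictly more extreme than
        the observed one (ties from permutations recreating the observed
        partition are unavoidable and still count toward p)."""
        if self.null_stats is None:
            raise ValueError("permutation_tests(..., keep_null=True) required")
        eps = 1e-9 * max(abs(self.mean_distance), float(np.abs(self.null_stats).max()), 1e-300)
        if self.is_within:
            return bool(self.null_stats.min() >= self.mean_distance - eps)
        return bool(self.null_stats.max() <= self.mean_distance + eps)


def _within_mean(values: np.ndarray, idx: np.ndarray) -> float:
    sub = values[np.ix_(idx, idx)]
    k = len(idx)
    return (sub.sum() - np.trace(sub)) / (k * (k - 1))


def permutation_tests(
    D: DistanceMatrix,
    groups: GroupAssignment,
    n_perm: int = 1999,
    seed: Optional[int] = None,
    keep_null: bool = False,
) -> list[GroupDistanceTest]:
    """Permutation tests for every group pair (separation) and every group of
    size >= 2 (compactness); see the module docstring for the two null
    schemes.  Fixed ``seed`` makes all p-values reproducible; ``keep_null``
    attaches the permutation statistics to each result."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = groups.groups
    pos = {a: i for i, a in enumerate(D.ids)}
    idx = {g: np.array([pos[a] for a in groups.members(g)]) for g in labels}
    rng = np.random.default_rng(seed)
    V = D.values
    out: list[GroupDistanceTest] = []
    # within-group compactness
    n = D.n
    for g in labels:
        ig = idx[g]
        if len(ig) < 2:
            continue
        obs = _within_mean(V, ig)
        null = np.empty(n_perm)
        for b in range(n_perm):
            sub = rng.choice(n, size=len(ig), replace=False)
            null[b] = _within_mean(V, sub)
        # ties counted with a scale-relative tolerance so that permutations
        # recreating the observed partition tie regardless of summation order
        eps = 1e-9 * max(abs(obs), float(np.abs(null).max()), 1e-300)
        p = (1 + int((null <= obs + eps).sum())) / (1 + n_perm)
        out.append(
            GroupDistanceTest(
                g, g, float(obs), p, n_perm, stars(p), null if keep_null else None
            )
        )
    # between-group separation
    for gi in range(len(labels)):
        for hj in range(gi + 1, len(labels)):
            g, h = labels[gi], labels[hj]
            ig, ih = idx[g], idx[h]
            pool = np.concatenate([ig, ih])
            kg = len(ig)
            obs = V[np.ix_(ig, ih)].mean()
            null = np.empty(n_perm)
            for b in range(n_perm):
                perm = rng.permutation(pool)
                null[b] = V[np.ix_(perm[:kg], perm[kg:])].mean()
            eps = 1e-9 * max(abs(obs), float(np.abs(null).max()), 1e-300)
            p = (1 + int((null >= obs - eps).sum())) / (1 + n_perm)
            out.append(
                GroupDistanceTest(
                    g, h, float(obs), p, n_perm, stars(p), null if keep_null else None
                )
            )
    return out
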