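"""Pairwise distances for polyploid marker panels.

The workhorse is Bruvo's stepwise distance for microsatellites: per allele
pair ``d = 1 - 2**(-x)`` with ``x = |a - b| / repeat_unit``, extended to the
allele multisets of a polyploid genotype by exact minimum-cost matching.
When two genotypes show different numbers of distinct alleles ("ploidy
independence"), virtual alleles fill the smaller genotype under a selectable
model:

``genome_addition``       fill with the smaller genotype's own alleles,
                          averaging over every possible fill;
``genome_loss``           fill with the larger genotype's alleles;
``addition_loss_average`` mean of the two (the default — both copy-number
                          change directions equally likely);
``infinite``              each unmatched slot scores the maximal distance 1.

The S-locus, multiallelic and non-stepwise, is compared as a set via the
Jaccard distance and enters the combined matrix as one locus among eleven.
Nei's standard distance on per-accession presence-split frequencies feeds the
dendrogram and the differentiation heatmap.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable

__all__ = [
    "FillModel",
    "DistanceMatrix",
    "bruvo_allele",
    "bruvo_locus",
    "jaccard_s",
    "combined_matrix",
    "nei_distance_matrix",
    "nei_locus_components",
    "NEI_MAX_DISTANCE",
]

#: distance reported when two accessions share no allelic identity at all
#: (the Nei log-ratio diverges); exp(-30) ~ 1e-13 identity.
NEI_MAX_DISTANCE = 30.0


class FillModel(str, Enum):
    INFINITE = "infinite"
    GENOME_ADDITION = "genome_addition"
    GENOME_LOSS = "genome_loss"
    ADDITION_LOSS_AVERAGE = "addition_loss_average"


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric accession-by-accession distance matrix with provenance."""

    ids: tuple[str, ...]
    values: np.ndarray
    metric_tag: str = ""
    per_locus: Optional[Mapping[str, np.ndarray]] = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "values", v)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} ids")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(np.isnan(v)) or np.any(np.isinf(v)):
            raise ValueError("distance matrix has non-finite entries")
        if np.any(v < -1e-12):
            raise ValueError("negative distances")
        if self.per_locus is not None:
            object.__setattr__(self, "per_locus", dict(self.per_locus))

    def __getitem__(self, pair):
        i, j = pair
        return self.values[self.ids.index(i), self.ids.index(j)]

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="accession")

    @classmethod
    def from_csv(cls, path, metric_tag: str = "") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(ids=tuple(df.index), values=df.to_numpy(float), metric_tag=metric_tag)

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{x:.6f}" for x in self.values[i])
                fh.write(f"{name:<12s} {row}\n")


# ---------------------------------------------------------------------------
# Bruvo distance
# ---------------------------------------------------------------------------


def bruvo_allele(a: float, b: float, unit: float) -> float:
    """Stepwise allele distance 1 - 2**(-|a-b|/unit); 0 iff a == b.

    Fractional repeat counts are allowed: off-ladder fragment sizes are
    legitimate inputs and the formula is well defined for real x.
    """
    if unit <= 0:
        raise ValueError("repeat unit must be positive")
    return 1.0 - 2.0 ** (-abs(a - b) / unit)


def _min_matching_mean(A: Sequence[float], B: Sequence[float], unit: float) -> float:
    """Minimum over all |A|! matchings of the mean allele distance (|A| == |B|)."""
    k = len(A)
    best = math.inf
    for perm in itertools.permutations(range(k)):
        tot = 0.0
        for i, j in enumerate(perm):
            tot += bruvo_allele(A[i], B[j], unit)
            if tot >= best:
                break
        best = min(best, tot)
    return best / k


def _infinite_model(A: Sequence[float], B: Sequence[float], unit: float) -> float:
    """Pad the smaller multiset with virtual alleles at distance 1 to all."""
    if len(A) > len(B):
        A, B = B, A
    k, m = len(A), len(B)
    best = math.inf
    # choose which alleles of B the real alleles of A match; the m-k leftover
    # slots each contribute 1
    for perm in itertools.permutations(range(m), k):
        tot = float(m - k)
        for i, j in enumerate(perm):
            tot += bruvo_allele(A[i], B[j], unit)
        best = min(best, tot)
    return best / m


def _fill_model(
    A: Sequence[float], B: Sequence[float], unit: float, donor: Sequence[float]
) -> float:
    """Average the matching distance over every fill of the smaller multiset
    with alleles drawn (with replacement) from ``donor``."""
    if len(A) > len(B):
        A, B = B, A
    deficit = len(B) - len(A)
    total = 0.0
    n_fills = 0
    for fill in itertools.product(donor, repeat=deficit):
        total += _min_matching_mean(tuple(A) + fill, B, unit)
        n_fills += 1
    return total / n_fills


def bruvo_locus(
    A: Sequence[float],
    B: Sequence[float],
    unit: float,
    ploidy: int = 4,
    model: FillModel = FillModel.ADDITION_LOSS_AVERAGE,
) -> float:
    """Bruvo distance between two allele multisets at one SSR locus.

    Matching is exact (brute force over at most ploidy! permutations, cheap
    at ploidy 4).  Multisets of unequal size are reconciled under ``model``.
    """
    A, B = tuple(A), tuple(B)
    if not A or not B:
        raise ValueError("bruvo_locus: empty allele multiset")
    if len(A) > ploidy or len(B) > ploidy:
        raise ValueError("bruvo_locus: multiset larger than ploidy")
    model = FillModel(model)
    if len(A) == len(B):
        return _min_matching_mean(A, B, unit)
    if model is FillModel.INFINITE:
        return _infinite_model(A, B, unit)
    small, large = (A, B) if len(A) < len(B) else (B, A)
    if model is FillModel.GENOME_ADDITION:
        return _fill_model(small, large, unit, donor=small)
    if model is FillModel.GENOME_LOSS:
        return _fill_model(small, large, unit, donor=large)
    add = _fill_model(small, large, unit, donor=small)
    loss = _fill_model(small, large, unit, donor=large)
    return 0.5 * (add + loss)


def jaccard_s(A, B) -> float:
    """Jaccard distance 1 - |A∩B| / |A∪B| between two S-allele sets."""
    A, B = frozenset(A), frozenset(B)
    if not A or not B:
        raise ValueError("jaccard_s: empty S-allele set")
    return 1.0 - len(A & B) / len(A | B)


# ---------------------------------------------------------------------------
# matrix builders
# ---------------------------------------------------------------------------


def combined_matrix(
    table: GenotypeTable, model: FillModel = FillModel.ADDITION_LOSS_AVERAGE
) -> DistanceMatrix:
    """Combined multilocus distance: mean of the per-locus Bruvo distances and
    the S-locus Jaccard distance, each locus weighted equally.

    Pairs with missing loci average over the loci both members are typed at;
    a pair sharing no typed locus is an error.  Per-locus matrices (NaN where
    a member is untyped) are kept for provenance.
    """
    if len(table) < 2:
        raise ValueError("combined_matrix needs at least 2 accessions")
    ids = table.accession_ids
    n = len(ids)
    loci = table.loci
    per_locus = {l.name: np.full((n, n), np.nan) for l in loci}
    for m in per_locus.values():
        np.fill_diagonal(m, 0.0)
    cache: dict[tuple, float] = {}
    accs = table.accessions
    for i in range(n):
        for j in range(i + 1, n):
            for l in loci:
                if l.marker_type == "s_locus":
                    a, b = accs[i].s_alleles, accs[j].s_alleles
                    if a is None or b is None:
                        continue
                    key = (l.name,) + tuple(sorted((tuple(sorted(a)), tuple(sorted(b)))))
                    d = cache.get(key)
                    if d is None:
                        d = jaccard_s(a, b)
                        cache[key] = d
                else:
                    a = accs[i].ssr_alleles.get(l.name)
                    b = accs[j].ssr_alleles.get(l.name)
                    if a is None or b is None:
                        continue
                    key = (l.name,) + tuple(sorted((a, b)))
                    d = cache.get(key)
                    if d is None:
                        d = bruvo_locus(a, b, l.repeat_unit, table.ploidy, model)
                        cache[key] = d
                per_locus[l.name][i, j] = per_locus[l.name][j, i] = d
    stack = np.stack([per_locus[l.name] for l in loci])
    shared = np.sum(~np.isnan(stack), axis=0)
    off = ~np.eye(n, dtype=bool)
    if np.any(shared[off] == 0):
        i, j = np.argwhere((shared == 0) & off)[0]
        raise ValueError(
            f"accessions {ids[i]!r} and {ids[j]!r} share no typed locus"
        )
    with np.errstate(invalid="ignore"):
        values = np.nanmean(stack, axis=0)
    np.fill_diagonal(values, 0.0)
    values = 0.5 * (values + values.T)
    return DistanceMatrix(
        ids=ids,
        values=values,
        metric_tag=f"combined_bruvo_jaccard[{FillModel(model).value}]",
        per_locus=per_locus,
    )


def nei_locus_components(
    table: GenotypeTable,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Per-locus building blocks of Nei's distance.

    Returns locus names, an (L, n, n) array of cross-identities
    J_xy^l = sum_i p_{x,i} p_{y,i} (NaN where a member is untyped), and an
    (L, n) array of self-identities J_x^l.  Summing blocks over any multiset
    of loci (e.g. a bootstrap draw) yields the corresponding Nei matrix.
    """
    from .diversity import _cell  # presence collapsing shared with diversity

    ids = table.accession_ids
    n = len(ids)
    loci = [l.name for l in table.loci]
    jxy = np.full((len(loci), n, n), np.nan)
    jx = np.full((len(loci), n), np.nan)
    for li, lname in enumerate(loci):
        cells = [_cell(table, acc, lname) for acc in table.accessions]
        for i, ci in enumerate(cells):
            if ci is None:
                continue
            jx[li, i] = sum((1.0 / len(ci)) ** 2 for _ in ci)
            for j in range(i, n):
                cj = cells[j]
                if cj is None:
                    continue
                shared = set(ci) & set(cj)
                v = sum((1.0 / len(ci)) * (1.0 / len(cj)) for _ in shared)
                jxy[li, i, j] = jxy[li, j, i] = v
    return loci, jxy, jx


def nei_from_components(
    jxy: np.ndarray, jx: np.ndarray, locus_idx: Optional[Sequence[int]] = None
) -> np.ndarray:
    """Nei standard distance D = -ln(J_xy / sqrt(J_x J_y)) from components,
    summing J's over the given loci (with repetition allowed)."""
    if locus_idx is None:
        locus_idx = range(jxy.shape[0])
    idx = np.fromiter(locus_idx, dtype=int)
    sel_xy = jxy[idx]
    sel_x = jx[idx]
    n = jxy.shape[1]
    # per pair, sum over loci typed in both members
    pair_ok = ~np.isnan(sel_xy)
    Jxy = np.where(pair_ok, sel_xy, 0.0).sum(axis=0)
    # self identities restricted to the loci contributing to each pair
    x_ok = ~np.isnan(sel_x)
    Jx = np.zeros((n, n))
    Jy = np.zeros((n, n))
    for li in range(len(idx)):
        ok = pair_ok[li]
        Jx += np.where(ok, np.where(x_ok[li], sel_x[li], 0.0)[:, None], 0.0)
        Jy += np.where(ok, np.where(x_ok[li], sel_x[li], 0.0)[None, :], 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        I = Jxy / np.sqrt(Jx * Jy)
        D = -np.log(I)
    D = np.where(np.isfinite(D), D, NEI_MAX_DISTANCE)
    D = np.minimum(D, NEI_MAX_DISTANCE)
    D = np.maximum(D, 0.0)  # clip -0.0 / rounding noise on identical pairs
    np.fill_diagonal(D, 0.0)
    return 0.5 * (D + D.T)


def nei_distance_matrix(table: GenotypeTable) -> DistanceMatrix:
    """Nei standard distance among accessions, each treated as a one-member
    population with presence-split allele frequencies; J's summed over all
    loci (S-locus included).  Pairs with no shared identity are capped at
    :data:`NEI_MAX_DISTANCE`."""
    if len(table) < 2:
        raise ValueError("nei_distance_matrix needs at least 2 accessions")
    _, jxy, jx = nei_locus_components(table)
    D = nei_from_components(jxy, jx)
    return DistanceMatrix(ids=table.accession_ids, values=D, metric_tag="nei_standard")
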