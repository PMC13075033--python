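"""Model-selection arithmetic on Bayesian-clustering run outputs.

The clustering runs themselves (e.g. STRUCTURE's admixture MCMC) are external;
this module consumes their numeric outputs: a long table of per-run
log-likelihoods ln P(D|K) and, optionally, per-run Q (membership) matrices.

Two complementary criteria for the number of clusters K are reported and never
auto-selected between:

* the Evanno rate-of-change statistic
  ΔK = |L''(K)| / sd(L(K)), with L'(K) = mean(K) - mean(K-1) and
  L''(K) = L'(K+1) - L'(K), which highlights the uppermost hierarchical
  level of structure; and
* the likelihood plateau: the smallest K beyond which the mean ln P(D|K)
  gains no more than a tolerance (default one standard deviation of L(K)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LikelihoodTable",
    "DeltaKResult",
    "QSummary",
    "evanno",
    "summarize_q",
]


@dataclass(frozen=True)
class LikelihoodTable:
    """Long-format records of (K, replicate, lnP)."""

    records: pd.DataFrame  # columns K, replicate, lnP

    def __post_init__(self):
        df = pd.DataFrame(self.records)[["K", "replicate", "lnP"]].copy()
        df["K"] = df["K"].astype(int)
        object.__setattr__(self, "records", df)
        ks = sorted(df["K"].unique())
        if len(ks) >= 2 and ks != list(range(ks[0], ks[-1] + 1)):
            raise ValueError("K values must span a contiguous range")
        counts = df.groupby("K").size()
        if counts.nunique() > 1:
            warnings.warn("unequal replicate counts across K", stacklevel=2)

    @classmethod
    def from_csv(cls, path) -> "LikelihoodTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @property
    def ks(self) -> np.ndarray:
        return np.array(sorted(self.records["K"].unique()))


@dataclass(frozen=True)
class DeltaKResult:
    ks: np.ndarray
    mean_lnP: np.ndarray
    sd_lnP: np.ndarray  # sample sd (ddof=1)
    L1: np.ndarray  # mean L'(K); NaN at the first K
    L2: np.ndarray  # |mean L''(K)|; NaN at both ends
    delta_k: np.ndarray  # L2 / sd; NaN at ends and where sd == 0
    optimal_K_deltaK: Optional[int]
    plateau_K: Optional[int]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "K": self.ks,
                "mean_lnP": self.mean_lnP,
                "sd_lnP": self.sd_lnP,
                "L1": self.L1,
                "L2": self.L2,
                "deltaK": self.delta_k,
            }
        )


def evanno(table: LikelihoodTable, plateau_tol_sd: float = 1.0) -> DeltaKResult:
    """Evanno ΔK and likelihood-plateau summaries of a run-likelihood table.

    Requires at least 3 consecutive K values and >= 2 replicates per K (for
    the standard deviation).  Interior K with sd = 0 get an undefined (NaN)
    ΔK rather than an infinity.  ``plateau_K`` is the smallest K such that no
    larger K improves the mean ln P(D|K) by more than
    ``plateau_tol_sd * sd(K)``.
    """
    df = table.records
    ks = table.ks
    if len(ks) < 3:
        raise ValueError("evanno needs at least 3 consecutive K values")
    grouped = df.groupby("K")["lnP"]
    if grouped.size().min() < 2:
        raise ValueError("evanno needs >= 2 replicates per K")
    mean = grouped.mean().reindex(ks).to_numpy()
    sd = grouped.std(ddof=1).reindex(ks).to_numpy()
    nK = len(ks)
    L1 = np.full(nK, np.nan)
    L2 = np.full(nK, np.nan)
    dk = np.full(nK, np.nan)
    L1[1:] = mean[1:] - mean[:-1]
    for i in range(1, nK - 1):
        L2[i] = abs(L1[i + 1] - L1[i])
        if sd[i] > 0:
            dk[i] = L2[i] / sd[i]
    optimal = None
    if np.any(np.isfinite(dk)):
        optimal = int(ks[int(np.nanargmax(dk))])
    plateau = None
    for i in range(nK):
        gain = mean[i + 1 :] - mean[i]
        if gain.size == 0 or np.all(gain <= plateau_tol_sd * sd[i]):
            plateau = int(ks[i])
            break
    return DeltaKResult(
        ks=ks,
        mean_lnP=mean,
        sd_lnP=sd,
        L1=L1,
        L2=L2,
        delta_k=dk,
        optimal_K_deltaK=optimal,
        plateau_K=plateau,
    )


@dataclass(frozen=True)
class QSummary:
    mean_q: np.ndarray  # accessions x K, rows sum to 1
    assignment: np.ndarray  # argmax cluster per accession
    admixed: np.ndarray  # True where max membership < threshold
    threshold: float


def _align_columns(ref: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Greedy column permutation of ``other`` maximizing correlation with the
    matching column of ``ref`` (label-switching repair across replicates)."""
    K = ref.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(ref.T, other.T)[:K, K:]
    C = np.nan_to_num(C, nan=0.0)  # constant columns carry no signal
    perm = np.full(K, -1)
    used_r, used_c = set(), set()
    flat = sorted(
        ((C[r, c], r, c) for r in range(K) for c in range(K)), reverse=True
    )
    for _, r, c in flat:
        if r in used_r or c in used_c:
            continue
        perm[r] = c
        used_r.add(r)
        used_c.add(c)
    return other[:, perm]


def summarize_q(
    q_matrices: Sequence[np.ndarray], admixed_threshold: float = 0.8
) -> QSummary:
    """Align replicate Q matrices to the first by greedy column correlation,
    average element-wise, and call each accession's cluster by row argmax;
    accessions whose maximum membership falls below ``admixed_threshold``
    are flagged admixed."""
    mats = [np.asarray(q, dtype=float) for q in q_matrices]
    if not mats:
        raise ValueError("no Q matrices")
    shape = mats[0].shape
    for q in mats:
        if q.shape != shape:
            raise ValueError("Q matrices differ in shape")
        if not np.allclose(q.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("Q matrix rows must sum to 1")
    ref = mats[0]
    aligned = [ref] + [_align_columns(ref, q) for q in mats[1:]]
    mean_q = np.mean(aligned, axis=0)
    mean_q = mean_q / mean_q.sum(axis=1, keepdims=True)
    assignment = mean_q.argmax(axis=1)
    admixed = mean_q.max(axis=1) < admixed_threshold
    return QSummary(
        mean_q=mean_q,
        assignment=assignment,
        admixed=admixed,
        threshold=admixed_threshold,
    )
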