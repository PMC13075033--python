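"""Synthetic tetraploid germplasm panels with known truth.

The generator emulates a small clonal-germplasm collection of the kind the
analysis stack targets: 27 tetraploid accessions in 5 groups (sizes
5/7/5/5/5), 10 SSR loci with ladders of 5-14 alleles spanning roughly
102-213 bp, and one 17-allele S-locus.  Group structure comes from
per-group Dirichlet allele frequencies over each ladder (concentration
``alpha``; small alpha = strong differentiation).  The default panel also
contains the features that make real germplasm panels awkward: exact clones,
single-allele clone mutants (one allele shifted by one repeat unit), and
admixed accessions drawing allele copies from a mixture of groups.

Dosage ambiguity is emulated by presence collapsing: each accession draws
``ploidy`` allele copies i.i.d. but only the distinct alleles are recorded,
exactly as in routine polyploid electropherogram scoring.  S-alleles are
drawn without replacement within an accession (self-incompatibility alleles
are distinct within a genotype).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .genotypes import (
    S_LOCUS,
    SSR,
    AccessionGenotype,
    GenotypeTable,
    GroupAssignment,
    LocusDef,
)
from .structure import LikelihoodTable

__all__ = [
    "LocusLadder",
    "CloneSpec",
    "AdmixSpec",
    "SimConfig",
    "SimTruth",
    "simulate_panel",
    "simulate_likelihood_runs",
]


@dataclass(frozen=True)
class LocusLadder:
    """Allele ladder of one simulated SSR locus."""

    name: str
    base_size: int
    repeat_unit: int
    n_alleles: int

    @property
    def sizes(self) -> np.ndarray:
        return self.base_size + self.repeat_unit * np.arange(self.n_alleles)


@dataclass(frozen=True)
class CloneSpec:
    """Overwrite the ``n_copies`` accessions following ``source`` in its
    group with copies of it, each mutated at ``n_mutated_alleles`` alleles
    by one repeat unit."""

    source: str
    n_copies: int
    n_mutated_alleles: int = 0


@dataclass(frozen=True)
class AdmixSpec:
    """Redraw one accession's allele copies from a mixture over groups."""

    accession: str
    proportions: tuple[float, ...]


def _default_clones() -> tuple[CloneSpec, ...]:
    # a clone complex in group 2 (3 exact copies + 3 single-allele mutants)
    # and one single-allele mutant clone pair in group 1
    return (
        CloneSpec("G2_A1", 3, 0),
        CloneSpec("G2_A1", 3, 1),
        CloneSpec("G1_A1", 1, 1),
    )


def _default_admixed() -> tuple[AdmixSpec, ...]:
    return (
        AdmixSpec("G4_A5", (0.0, 0.0, 0.5, 0.5, 0.0)),
        AdmixSpec("G5_A5", (0.3, 0.0, 0.0, 0.0, 0.7)),
    )


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_groups: int = 5
    accessions_per_group: tuple[int, ...] = (5, 7, 5, 5, 5)
    n_ssr_loci: int = 10
    ploidy: int = 4
    ladders: Optional[tuple[LocusLadder, ...]] = None  # auto-drawn when None
    ladder_size_range: tuple[int, int] = (102, 213)
    ladder_allele_range: tuple[int, int] = (5, 14)
    alpha: float = 0.5
    clone_specs: tuple[CloneSpec, ...] = field(default_factory=_default_clones)
    admixed_specs: tuple[AdmixSpec, ...] = field(default_factory=_default_admixed)
    s_pool_size: int = 17
    s_alleles_range: tuple[int, int] = (2, 4)
    s_alpha: float = 0.5
    dropout_rate: float = 0.0

    def __post_init__(self):
        if len(self.accessions_per_group) != self.n_groups:
            raise ValueError("accessions_per_group must have n_groups entries")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.alpha <= 0 or self.s_alpha <= 0:
            raise ValueError("Dirichlet concentrations must be positive")


@dataclass(frozen=True)
class SimTruth:
    group_labels: dict[str, str]  # accession -> group
    freqs: dict[tuple[str, str], np.ndarray]  # (group, locus) -> ladder freqs
    clone_map: dict[str, str]  # clone accession -> source accession
    admixture: dict[str, tuple[float, ...]]  # accession -> group proportions
    ladders: tuple[LocusLadder, ...]
    s_pool: tuple[str, ...]


def _draw_ladders(cfg: SimConfig, rng: np.random.Generator) -> tuple[LocusLadder, ...]:
    lo, hi = cfg.ladder_size_range
    ladders = []
    for i in range(cfg.n_ssr_loci):
        unit = int(rng.choice([2, 3]))
        n_alleles = int(rng.integers(cfg.ladder_allele_range[0], cfg.ladder_allele_range[1] + 1))
        span = unit * (n_alleles - 1)
        base = int(rng.integers(lo, max(lo + 1, hi - span)))
        ladders.append(
            LocusLadder(name=f"SSR{i + 1:02d}", base_size=base, repeat_unit=unit, n_alleles=n_alleles)
        )
    return tuple(ladders)


def _draw_cell(
    ladder: LocusLadder,
    weights: np.ndarray,
    rng: np.random.Generator,
    ploidy: int,
    dropout: float,
) -> Optional[tuple[int, ...]]:
    copies = rng.choice(ladder.sizes, size=ploidy, p=weights)
    if dropout > 0:
        keep = rng.random(ploidy) >= dropout
        copies = copies[keep]
    if copies.size == 0:
        return None
    return tuple(sorted(set(int(c) for c in copies)))


def simulate_panel(config: SimConfig) -> tuple[GenotypeTable, SimTruth]:
    """Simulate a genotype panel plus the ground truth used to generate it.

    Same seed, same config -> byte-identical genotype CSV on write.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    ladders = cfg.ladders if cfg.ladders is not None else _draw_ladders(cfg, rng)
    for lad in ladders:
        if lad.n_alleles < 2:
            raise ValueError(f"ladder {lad.name}: too few alleles")
    group_names = [f"G{g + 1}" for g in range(cfg.n_groups)]
    # per (group, locus) Dirichlet frequencies over the ladder
    freqs: dict[tuple[str, str], np.ndarray] = {}
    for g in group_names:
        for lad in ladders:
            freqs[(g, lad.name)] = rng.dirichlet(np.full(lad.n_alleles, cfg.alpha))
    # group-biased S-allele weights
    s_pool = tuple(f"S{i + 1:02d}" for i in range(cfg.s_pool_size))
    s_weights = {g: rng.dirichlet(np.full(cfg.s_pool_size, cfg.s_alpha)) for g in group_names}

    accessions: list[AccessionGenotype] = []
    labels: dict[str, str] = {}
    order: dict[str, list[str]] = {}
    for gi, g in enumerate(group_names):
        order[g] = []
        for ai in range(cfg.accessions_per_group[gi]):
            acc_id = f"{g}_A{ai + 1}"
            order[g].append(acc_id)
            labels[acc_id] = g
            cells: dict[str, tuple[int, ...]] = {}
            for lad in ladders:
                cell = _draw_cell(lad, freqs[(g, lad.name)], rng, cfg.ploidy, cfg.dropout_rate)
                if cell is not None:
                    cells[lad.name] = cell
            k = int(rng.integers(cfg.s_alleles_range[0], cfg.s_alleles_range[1] + 1))
            s_set = frozenset(rng.choice(s_pool, size=k, replace=False, p=s_weights[g]))
            accessions.append(
                AccessionGenotype(accession_id=acc_id, group=g, ssr_alleles=cells, s_alleles=s_set)
            )
    by_id = {a.accession_id: a for a in accessions}

    # admixed accessions: redraw copies from a mixture over group frequencies
    admixture: dict[str, tuple[float, ...]] = {}
    for spec in cfg.admixed_specs:
        if spec.accession not in by_id:
            raise ValueError(f"admixed accession {spec.accession!r} not in panel")
        props = np.asarray(spec.proportions, dtype=float)
        if props.shape != (cfg.n_groups,) or not np.isclose(props.sum(), 1.0):
            raise ValueError(f"admix proportions for {spec.accession!r} must sum to 1")
        cells = {}
        for lad in ladders:
            w = sum(p * freqs[(g, lad.name)] for p, g in zip(props, group_names))
            cell = _draw_cell(lad, w / w.sum(), rng, cfg.ploidy, cfg.dropout_rate)
            if cell is not None:
                cells[lad.name] = cell
        sw = sum(p * s_weights[g] for p, g in zip(props, group_names))
        k = int(rng.integers(cfg.s_alleles_range[0], cfg.s_alleles_range[1] + 1))
        s_set = frozenset(rng.choice(s_pool, size=k, replace=False, p=sw / sw.sum()))
        old = by_id[spec.accession]
        by_id[spec.accession] = replace(old, ssr_alleles=cells, s_alleles=s_set)
        admixture[spec.accession] = tuple(props)

    # clones: overwrite the accessions following the source within its group
    clone_map: dict[str, str] = {}
    cursor: dict[str, int] = {}
    for spec in cfg.clone_specs:
        if spec.source not in by_id:
            raise ValueError(f"clone source {spec.source!r} not in panel")
        g = labels[spec.source]
        start = cursor.get(spec.source, order[g].index(spec.source) + 1)
        targets = order[g][start : start + spec.n_copies]
        if len(targets) < spec.n_copies:
            raise ValueError(
                f"group {g!r} too small for {spec.n_copies} clone(s) of {spec.source!r}"
            )
        cursor[spec.source] = start + spec.n_copies
        src = by_id[spec.source]
        for tgt in targets:
            cells = {loc: cell for loc, cell in src.ssr_alleles.items()}
            for _ in range(spec.n_mutated_alleles):
                loc = str(rng.choice(sorted(cells)))
                lad = next(l for l in ladders if l.name == loc)
                cell = list(cells[loc])
                pos = int(rng.integers(len(cell)))
                step = lad.repeat_unit * int(rng.choice([-1, 1]))
                mutated = cell[pos] + step
                if mutated in cell:  # keep the mutant visibly different
                    mutated = cell[pos] - step
                cell[pos] = mutated
                cells[loc] = tuple(sorted(set(cell)))
            by_id[tgt] = replace(
                by_id[tgt], ssr_alleles=cells, s_alleles=src.s_alleles
            )
            clone_map[tgt] = spec.source

    locus_defs = tuple(
        LocusDef(
            name=lad.name,
            marker_type=SSR,
            repeat_unit=lad.repeat_unit,
            size_range=(int(lad.sizes.min()) - lad.repeat_unit, int(lad.sizes.max()) + lad.repeat_unit),
        )
        for lad in ladders
    ) + (LocusDef(name="S_locus", marker_type=S_LOCUS),)
    table = GenotypeTable(
        loci=locus_defs,
        accessions=tuple(by_id[a.accession_id] for a in accessions),
        ploidy=cfg.ploidy,
    )
    truth = SimTruth(
        group_labels=labels,
        freqs=freqs,
        clone_map=clone_map,
        admixture=admixture,
        ladders=ladders,
        s_pool=s_pool,
    )
    return table, truth


def simulate_likelihood_runs(
    true_K: int,
    k_range: tuple[int, int] = (1, 10),
    replicates: int = 20,
    noise_sd: float = 15.0,
    seed: Optional[int] = None,
    base_lnP: float = -6000.0,
    gain_per_K: float = 300.0,
    plateau_gain: float = 1.0,
) -> LikelihoodTable:
    """Synthetic run-likelihood table with a plateau at ``true_K``.

    The mean ln P(D|K) curve is piecewise linear: it gains ``gain_per_K``
    per cluster up to ``true_K`` and only ``plateau_gain`` per cluster
    beyond, plus i.i.d. Gaussian replicate noise of ``noise_sd``.
    """
    lo, hi = k_range
    if not lo < true_K < hi:
        raise ValueError("true_K must lie in the interior of k_range")
    if replicates < 2:
        raise ValueError("need >= 2 replicates per K")
    rng = np.random.default_rng(seed)
    rows = []
    for K in range(lo, hi + 1):
        mean = base_lnP + gain_per_K * min(K, true_K) + plateau_gain * max(0, K - true_K)
        for r in range(replicates):
            rows.append(
                {"K": K, "replicate": r + 1, "lnP": mean + rng.normal(0.0, noise_sd)}
            )
    import pandas as pd

    return LikelihoodTable(pd.DataFrame(rows))
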