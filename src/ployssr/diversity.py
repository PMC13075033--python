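"""Per-locus and per-group diversity statistics for polyploid marker panels.

Because allele dosage is ambiguous in tetraploid SSR scoring, frequencies are
computed from allele *presence*: by default every typed accession contributes
total weight 1 at a locus, split equally over its distinct observed alleles
(``presence_split``).  All downstream indices (Ne, PIC, Shannon H', resolving
power Rp) are functions of those presence-based frequencies, deliberately
avoiding dosage-dependent heterozygosity estimators.

Metrics
-------
Na     number of observed alleles
Ne     effective number of alleles, 1 / sum(p_i^2)
PA     private alleles: alleles carried by exactly one accession
PIC    polymorphic information content (Botstein):
       1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2
H'     Shannon information index, -sum(p_i ln p_i)
Rp     resolving power, sum over alleles of I_b = 1 - 2|0.5 - p|,
       with p the proportion of accessions carrying the allele
PI/PD  multilocus probability of identity and discrimination power; per locus
       PI_l = sum over distinct unordered allele-set phenotypes g of f_g^2,
       multiplied across loci.  This is a phenotype-match probability:
       allele-level diploid PI formulas do not apply to tetraploid phenotypes.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .genotypes import S_LOCUS, GenotypeTable, GroupAssignment

__all__ = [
    "AlleleFrequencies",
    "LocusStats",
    "IdentityResult",
    "GroupSummary",
    "allele_frequencies",
    "locus_stats",
    "all_locus_stats",
    "mean_stats",
    "probability_of_identity",
    "group_summaries",
]

METRICS = ("Na", "Ne", "PA", "PIC", "Hprime", "Rp")


def _cell(table: GenotypeTable, acc, locus_name: str):
    """Distinct observed alleles of one accession at one locus, or None."""
    if table.s_locus is not None and locus_name == table.s_locus.name:
        return tuple(sorted(acc.s_alleles)) if acc.s_alleles is not None else None
    raw = acc.ssr_alleles.get(locus_name)
    return tuple(sorted(set(raw))) if raw is not None else None


@dataclass(frozen=True)
class AlleleFrequencies:
    locus: str
    freqs: Mapping[object, float]
    carrier_props: Mapping[object, float]
    n_accessions_typed: int

    def __post_init__(self):
        object.__setattr__(self, "freqs", dict(self.freqs))
        object.__setattr__(self, "carrier_props", dict(self.carrier_props))


@dataclass(frozen=True)
class LocusStats:
    locus: str
    Na: int
    Ne: float
    PA: int
    PIC: float
    Hprime: float
    Rp: float


@dataclass(frozen=True)
class IdentityResult:
    per_locus_PI: Mapping[str, float]
    PI: float
    PD: float

    def __post_init__(self):
        object.__setattr__(self, "per_locus_PI", dict(self.per_locus_PI))


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n_accessions: int
    Na_total: int
    avg_alleles_per_locus: float
    PA_group: int
    avg_private_per_locus: float
    pct_polymorphic_loci: float

    @classmethod
    def from_totals(
        cls,
        group: str,
        n_accessions: int,
        na_total: int,
        pa_group: int,
        n_polymorphic_loci: int,
        n_loci: int,
    ) -> "GroupSummary":
        """Derive the per-locus averages and polymorphism percentage from
        within-group totals (single source of the aggregation arithmetic)."""
        return cls(
            group=group,
            n_accessions=n_accessions,
            Na_total=na_total,
            avg_alleles_per_locus=na_total / n_loci,
            PA_group=pa_group,
            avg_private_per_locus=pa_group / n_loci,
            pct_polymorphic_loci=100.0 * n_polymorphic_loci / n_loci,
        )


def allele_frequencies(
    table: GenotypeTable, locus: str, freq_mode: str = "presence_split"
) -> AlleleFrequencies:
    """Presence-based allele frequencies at one locus.

    ``presence_split`` (default): each typed accession carries weight 1 split
    equally among its distinct alleles, so frequencies sum to 1.
    ``presence_unit``: unnormalized carrier proportions (each accession counts
    once per allele it carries); these do not sum to 1 and feed Rp-style uses.
    """
    table.locus(locus)  # raises KeyError for undeclared loci
    weight: Counter = Counter()
    carriers: Counter = Counter()
    n_typed = 0
    for acc in table:
        cell = _cell(table, acc, locus)
        if cell is None:
            continue
        n_typed += 1
        for a in cell:
            carriers[a] += 1
            if freq_mode == "presence_split":
                weight[a] += 1.0 / len(cell)
            elif freq_mode == "presence_unit":
                weight[a] += 1.0
            else:
                raise ValueError(f"unknown freq_mode {freq_mode!r}")
    if n_typed == 0:
        raise ValueError(f"locus {locus!r} is untyped in every accession")
    freqs = {a: w / n_typed for a, w in weight.items()}
    props = {a: c / n_typed for a, c in carriers.items()}
    return AlleleFrequencies(
        locus=locus, freqs=freqs, carrier_props=props, n_accessions_typed=n_typed
    )


def locus_stats(freqs: AlleleFrequencies, table: GenotypeTable) -> LocusStats:
    """Diversity indices at one locus from presence-based frequencies."""
    p = [v for v in freqs.freqs.values() if v > 0]
    s2 = sum(x * x for x in p)
    s4 = sum(x ** 4 for x in p)
    pic = 1.0 - s2 - (s2 * s2 - s4)  # Botstein: 1 - Σp² - Σ_{i<j} 2 p_i² p_j²
    hprime = -sum(x * math.log(x) for x in p)
    rp = sum(1.0 - 2.0 * abs(0.5 - c) for c in freqs.carrier_props.values())
    # private alleles: carried by exactly one accession
    carriers: Counter = Counter()
    for acc in table:
        cell = _cell(table, acc, freqs.locus)
        if cell is None:
            continue
        for a in cell:
            carriers[a] += 1
    pa = sum(1 for c in carriers.values() if c == 1)
    return LocusStats(
        locus=freqs.locus,
        Na=len(p),
        Ne=1.0 / s2,
        PA=pa,
        PIC=pic,
        Hprime=hprime,
        Rp=rp,
    )


def all_locus_stats(
    table: GenotypeTable, freq_mode: str = "presence_split"
) -> list[LocusStats]:
    return [
        locus_stats(allele_frequencies(table, l.name, freq_mode), table)
        for l in table.loci
    ]


def mean_stats(
    stats: Sequence[LocusStats], subset: Optional[Sequence[str]] = None
) -> dict[str, float]:
    """Arithmetic mean of each diversity metric over a subset of loci."""
    if subset is not None:
        keep = set(subset)
        stats = [s for s in stats if s.locus in keep]
    if not stats:
        raise ValueError("mean_stats: empty locus subset")
    return {m: sum(getattr(s, m) for s in stats) / len(stats) for m in METRICS}


def probability_of_identity(table: GenotypeTable) -> IdentityResult:
    """Multilocus probability that two random accessions share a phenotype.

    Per locus, PI is the sum of squared frequencies of the distinct unordered
    allele-set phenotypes among typed accessions; the multilocus PI is the
    product over loci and PD = 1 - PI.
    """
    if len(table) < 2:
        raise ValueError("probability_of_identity needs at least 2 accessions")
    per_locus: dict[str, float] = {}
    for l in table.loci:
        phenos: Counter = Counter()
        n = 0
        for acc in table:
            cell = _cell(table, acc, l.name)
            if cell is None:
                continue
            phenos[cell] += 1
            n += 1
        if n == 0:
            continue
        per_locus[l.name] = sum((c / n) ** 2 for c in phenos.values())
    pi = math.prod(per_locus.values())
    return IdentityResult(per_locus_PI=per_locus, PI=pi, PD=1.0 - pi)


def group_summaries(
    table: GenotypeTable, groups: GroupAssignment
) -> list[GroupSummary]:
    """Within-group allelic diversity over all loci (S-locus included).

    ``PA_group`` counts alleles observed in exactly one group — a different
    universe from the accession-private PA of :func:`locus_stats`.
    """
    groups.validate_against(table)
    n_loci = len(table.loci)
    # (group, locus) -> set of alleles
    by_group: dict[str, dict[str, set]] = {g: {} for g in groups.groups}
    n_members: Counter = Counter()
    for acc in table:
        g = groups.assignments.get(acc.accession_id)
        if g is None:
            continue
        n_members[g] += 1
        for l in table.loci:
            cell = _cell(table, acc, l.name)
            if cell is None:
                continue
            by_group[g].setdefault(l.name, set()).update(cell)
    # which groups carry each (locus, allele)
    carrier_groups: dict[tuple, set] = {}
    for g, per_locus in by_group.items():
        for loc, alleles in per_locus.items():
            for a in alleles:
                carrier_groups.setdefault((loc, a), set()).add(g)
    out = []
    for g in groups.groups:
        if n_members[g] < 2:
            warnings.warn(
                f"group {g!r} has {n_members[g]} accession(s); "
                "within-group polymorphism is weakly informative",
                stacklevel=2,
            )
        na_total = sum(len(s) for s in by_group[g].values())
        pa = sum(1 for k, gs in carrier_groups.items() if gs == {g})
        poly = sum(1 for s in by_group[g].values() if len(s) >= 2)
        out.append(
            GroupSummary.from_totals(
                group=g,
                n_accessions=n_members[g],
                na_total=na_total,
                pa_group=pa,
                n_polymorphic_loci=poly,
                n_loci=n_loci,
            )
        )
    return out
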