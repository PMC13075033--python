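"""Presence-based diversity statistics, identity probability, group summaries."""

import itertools
import math

import numpy as np
import pytest

from ployssr.diversity import (
    GroupSummary,
    all_locus_stats,
    allele_frequencies,
    group_summaries,
    locus_stats,
    mean_stats,
    probability_of_identity,
)
from ployssr.genotypes import (
    AccessionGenotype,
    GenotypeTable,
    GroupAssignment,
    LocusDef,
)


def _ssr_table(cells, ploidy=4):
    """Single-locus table from a list of allele tuples."""
    loci = (LocusDef("L", "ssr", repeat_unit=2),)
    accs = tuple(
        AccessionGenotype(f"a{i}", None, {"L": c} if c else {}, None)
        for i, c in enumerate(cells)
    )
    return GenotypeTable(loci=loci, accessions=accs, ploidy=ploidy)


def test_presence_split_weighting():
    """Genotypes {A} and {A,B}: A gets (1 + 0.5)/2, B gets 0.5/2."""
    t = _ssr_table([(100,), (100, 102)])
    f = allele_frequencies(t, "L")
    assert f.freqs[100] == pytest.approx(0.75)
    assert f.freqs[102] == pytest.approx(0.25)
    assert f.carrier_props == {100: 1.0, 102: 0.5}
    assert f.n_accessions_typed == 2


def test_monomorphic_and_symmetric_frequencies():
    t = _ssr_table([(100,), (100,)])
    f = allele_frequencies(t, "L")
    assert f.freqs == {100: 1.0} and f.carrier_props == {100: 1.0}
    # 4 accessions x 4 distinct alleles, all 16 different -> each p = 1/16
    cells = [tuple(100 + 2 * (4 * i + j) for j in range(4)) for i in range(4)]
    f = allele_frequencies(_ssr_table(cells), "L")
    assert all(v == pytest.approx(1 / 16) for v in f.freqs.values())
    assert len(f.freqs) == 16


def test_frequencies_sum_to_one_on_panel(panel):
    table, _ = panel
    for locus in table.loci:
        f = allele_frequencies(table, locus.name)
        assert sum(f.freqs.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(0 < c <= 1 for c in f.carrier_props.values())


def test_locus_stats_closed_forms():
    # k equifrequent alleles -> Ne = k, H' = ln k
    k = 5
    t = _ssr_table([(100 + 2 * i,) for i in range(k)])
    s = locus_stats(allele_frequencies(t, "L"), t)
    assert s.Na == k
    assert s.Ne == pytest.approx(k)
    assert s.Hprime == pytest.approx(math.log(k))
    assert s.PA == k  # every allele carried by exactly one accession
    # two alleles p = q = 0.5 -> Botstein PIC = 0.375
    t2 = _ssr_table([(100,), (102,)])
    s2 = locus_stats(allele_frequencies(t2, "L"), t2)
    assert s2.PIC == pytest.approx(0.375)


def test_resolving_power_endpoints():
    # allele carried by every accession -> I_b = 0; carried by half -> I_b = 1
    t = _ssr_table([(100, 102), (100,)])
    s = locus_stats(allele_frequencies(t, "L"), t)
    # carriers: 100 by both (I_b = 0), 102 by one of two (I_b = 1)
    assert s.Rp == pytest.approx(1.0)


def test_ne_bounded_by_na_with_equality_iff_equifrequent(panel):
    table, _ = panel
    for s in all_locus_stats(table):
        assert 1 <= s.Ne <= s.Na + 1e-9
        assert 0 <= s.PIC < 1
        assert s.Hprime >= 0 and s.Rp >= 0 and s.PA <= s.Na


def test_pic_below_expected_heterozygosity(panel):
    table, _ = panel
    for locus in table.loci:
        f = allele_frequencies(table, locus.name)
        he = 1 - sum(v * v for v in f.freqs.values())
        s = locus_stats(f, table)
        if s.Na > 1:
            assert s.PIC < he + 1e-12


def test_mean_stats_of_printed_rp_column():
    """Averaging the ten per-locus SSR resolving powers gives 2.40."""
    rps = [0.519, 2.593, 1.852, 0.593, 4.222, 2.296, 2.148, 3.704, 2.815, 3.259]
    from ployssr.diversity import LocusStats

    # only Rp matters for this mean; other metrics filled with neutrals
    stats = [
        LocusStats(locus=f"L{i}", Na=1, Ne=1.0, PA=0, PIC=0.0, Hprime=0.0, Rp=r)
        for i, r in enumerate(rps)
    ]
    means = mean_stats(stats)
    assert round(means["Rp"], 2) == 2.40


def test_mean_stats_identity_and_errors():
    t = _ssr_table([(100,), (102,)])
    s = locus_stats(allele_frequencies(t, "L"), t)
    assert mean_stats([s]) == {m: getattr(s, m) for m in ("Na", "Ne", "PA", "PIC", "Hprime", "Rp")}
    with pytest.raises(ValueError):
        mean_stats([s], subset=["nope"])


def test_probability_of_identity_examples():
    # all accessions identical everywhere -> PI = 1, PD = 0
    t = _ssr_table([(100, 102), (100, 102)])
    r = probability_of_identity(t)
    assert r.PI == pytest.approx(1.0) and r.PD == pytest.approx(0.0)
    # 2 accessions, all loci distinct phenotypes -> PI = 0.5 ** L
    loci = tuple(LocusDef(f"L{i}", "ssr", repeat_unit=2) for i in range(3))
    accs = (
        AccessionGenotype("a", None, {f"L{i}": (100,) for i in range(3)}, None),
        AccessionGenotype("b", None, {f"L{i}": (102,) for i in range(3)}, None),
    )
    r = probability_of_identity(GenotypeTable(loci=loci, accessions=accs))
    assert r.PI == pytest.approx(0.5 ** 3)
    # a monomorphic locus contributes factor 1
    accs2 = (
        AccessionGenotype("a", None, {"L0": (100,), "L1": (100,)}, None),
        AccessionGenotype("b", None, {"L0": (102,), "L1": (100,)}, None),
    )
    r2 = probability_of_identity(GenotypeTable(loci=loci[:2], accessions=accs2))
    assert r2.per_locus_PI["L1"] == pytest.approx(1.0)
    assert r2.PI == pytest.approx(0.5)


def test_pi_matches_pair_enumeration_oracle(panel):
    """Per-locus PI equals the empirical probability that two accessions
    drawn uniformly with replacement share the phenotype."""
    table, _ = panel
    from ployssr.diversity import _cell

    r = probability_of_identity(table)
    for locus in table.loci:
        cells = [c for c in (_cell(table, a, locus.name) for a in table) if c is not None]
        n = len(cells)
        matches = sum(
            1 for a, b in itertools.product(cells, repeat=2) if a == b
        )
        assert r.per_locus_PI[locus.name] == pytest.approx(matches / n ** 2, abs=1e-12)


def test_pi_monotone_and_log_additive(panel):
    table, _ = panel
    r = probability_of_identity(table)
    running = 1.0
    for locus in table.loci:
        nxt = running * r.per_locus_PI[locus.name]
        assert nxt <= running + 1e-15
        running = nxt
    assert math.log(r.PI) == pytest.approx(
        sum(math.log(v) for v in r.per_locus_PI.values())
    )


def test_group_summary_from_totals_matches_printed_arithmetic():
    """Aggregation over 11 loci: 83 alleles -> 7.55/locus, 15 private -> 1.36."""
    g5 = GroupSummary.from_totals("G5", 5, 83, 26, 11, 11)
    assert round(g5.avg_alleles_per_locus, 2) == 7.55
    g1 = GroupSummary.from_totals("G1", 5, 54, 15, 11, 11)
    assert round(g1.avg_private_per_locus, 2) == 1.36
    g4 = GroupSummary.from_totals("G4", 5, 55, 3, 10, 11)
    assert round(g4.avg_alleles_per_locus, 2) == 5.00
    assert g1.pct_polymorphic_loci == 100.0


def test_group_summaries_clone_group_is_monomorphic():
    loci = (LocusDef("L1", "ssr", repeat_unit=2), LocusDef("L2", "ssr", repeat_unit=2))
    clone = {"L1": (100,), "L2": (120,)}
    accs = (
        AccessionGenotype("c1", "A", clone, None),
        AccessionGenotype("c2", "A", clone, None),
        AccessionGenotype("d1", "B", {"L1": (104, 110), "L2": (126, 132)}, None),
        AccessionGenotype("d2", "B", {"L1": (104, 112), "L2": (126, 135)}, None),
    )
    t = GenotypeTable(loci=loci, accessions=accs)
    out = {g.group: g for g in group_summaries(t, GroupAssignment.from_table(t))}
    assert out["A"].pct_polymorphic_loci == 0.0
    assert out["B"].pct_polymorphic_loci == 100.0
    # every allele is private to at most one group; totals are consistent
    assert out["A"].PA_group + out["B"].PA_group <= out["A"].Na_total + out["B"].Na_total


def test_group_private_alleles_disjoint(panel):
    table, truth = panel
    ga = GroupAssignment.from_table(table)
    out = group_summaries(table, ga)
    total_pa = sum(g.PA_group for g in out)
    # each (locus, allele) credited to at most one group
    seen = set()
    for g in out:
        assert g.avg_alleles_per_locus == pytest.approx(g.Na_total / len(table.loci))
    assert total_pa <= sum(g.Na_total for g in out)
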