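"""Bruvo, Jaccard, combined, and Nei distance engines."""

import itertools

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from ployssr.distance import (
    NEI_MAX_DISTANCE,
    DistanceMatrix,
    FillModel,
    bruvo_allele,
    bruvo_locus,
    combined_matrix,
    jaccard_s,
    nei_distance_matrix,
)
from ployssr.genotypes import AccessionGenotype, GenotypeTable, LocusDef


def _assignment_oracle(A, B, unit):
    """Independent minimum-matching via the Hungarian algorithm."""
    C = np.array([[bruvo_allele(a, b, unit) for b in B] for a in A])
    r, c = linear_sum_assignment(C)
    return C[r, c].sum() / len(A)


def _padded_oracle(A, B, unit):
    """Hungarian assignment with virtual alleles at distance 1 (infinite model)."""
    small, large = (A, B) if len(A) <= len(B) else (B, A)
    m = len(large)
    C = np.ones((m, m))
    for i, a in enumerate(small):
        for j, b in enumerate(large):
            C[i, j] = bruvo_allele(a, b, unit)
    r, c = linear_sum_assignment(C)
    return C[r, c].sum() / m


def test_bruvo_allele_closed_forms():
    assert bruvo_allele(150, 150, 2) == 0.0
    assert bruvo_allele(150, 152, 2) == pytest.approx(0.5)
    assert bruvo_allele(150, 158, 2) == pytest.approx(0.9375)
    with pytest.raises(ValueError):
        bruvo_allele(150, 152, 0)


def test_bruvo_allele_monotone_in_gap():
    unit = 3
    gaps = np.arange(0, 40)
    vals = [bruvo_allele(100, 100 + g, unit) for g in gaps]
    assert all(b >= a for a, b in zip(vals, vals[1:]))
    assert all(0 <= v < 1 for v in vals)


def test_bruvo_locus_equal_sizes_examples():
    assert bruvo_locus((150, 152), (150, 152), 2) == 0.0
    # min over the two matchings of {150,152} vs {150,154}: (0 + 0.5)/2
    assert bruvo_locus((150, 152), (150, 154), 2) == pytest.approx(0.25)


def test_bruvo_locus_fill_models_on_nested_genotypes():
    A, B = (150,), (150, 152)
    assert bruvo_locus(A, B, 2, model=FillModel.INFINITE) == pytest.approx(0.5)
    assert bruvo_locus(A, B, 2, model=FillModel.GENOME_ADDITION) == pytest.approx(0.25)
    assert bruvo_locus(A, B, 2, model=FillModel.GENOME_LOSS) == pytest.approx(0.125)
    assert bruvo_locus(A, B, 2, model=FillModel.ADDITION_LOSS_AVERAGE) == pytest.approx(0.1875)


def test_bruvo_locus_empty_multiset_is_error():
    with pytest.raises(ValueError):
        bruvo_locus((), (150,), 2)


def test_bruvo_matches_hungarian_oracle_equal_sizes():
    rng = np.random.default_rng(42)
    for _ in range(300):
        k = int(rng.integers(1, 5))
        A = tuple(int(a) for a in 100 + 2 * rng.integers(0, 12, size=k))
        B = tuple(int(b) for b in 100 + 2 * rng.integers(0, 12, size=k))
        got = bruvo_locus(A, B, 2)
        assert got == pytest.approx(_assignment_oracle(A, B, 2), abs=1e-12)


def test_bruvo_infinite_matches_padded_hungarian_oracle():
    rng = np.random.default_rng(7)
    for _ in range(200):
        ka, kb = int(rng.integers(1, 5)), int(rng.integers(1, 5))
        A = tuple(int(a) for a in 100 + 3 * rng.integers(0, 10, size=ka))
        B = tuple(int(b) for b in 100 + 3 * rng.integers(0, 10, size=kb))
        got = bruvo_locus(A, B, 3, model=FillModel.INFINITE)
        assert got == pytest.approx(_padded_oracle(A, B, 3), abs=1e-12)


def test_fill_model_ordering_infinite_dominates_average():
    rng = np.random.default_rng(5)
    for _ in range(100):
        ka = int(rng.integers(1, 4))
        A = tuple(sorted(int(a) for a in 100 + 2 * rng.integers(0, 8, size=ka)))
        B = tuple(sorted(set(A) | {int(100 + 2 * rng.integers(0, 8))}))
        if len(B) > 4 or len(A) == len(B):
            continue
        inf = bruvo_locus(A, B, 2, model=FillModel.INFINITE)
        avg = bruvo_locus(A, B, 2, model=FillModel.ADDITION_LOSS_AVERAGE)
        assert inf >= avg - 1e-12


def test_jaccard_examples():
    assert jaccard_s({"S1", "S4"}, {"S1", "S4"}) == 0.0
    assert jaccard_s({"S1"}, {"S2", "S3"}) == 1.0
    assert jaccard_s({"S1", "S4"}, {"S4", "S6"}) == pytest.approx(2 / 3)
    with pytest.raises(ValueError):
        jaccard_s(set(), {"S1"})


def _pair_table(a_cells, b_cells, a_s, b_s, n_loci=10):
    loci = tuple(LocusDef(f"L{i}", "ssr", repeat_unit=2) for i in range(n_loci)) + (
        LocusDef("S", "s_locus"),
    )
    accs = (
        AccessionGenotype("x", None, {f"L{i}": a_cells for i in range(n_loci)}, frozenset(a_s)),
        AccessionGenotype("y", None, {f"L{i}": b_cells for i in range(n_loci)}, frozenset(b_s)),
    )
    return GenotypeTable(loci=loci, accessions=accs)


def test_combined_matrix_s_locus_weight_is_one_eleventh():
    """Identical SSRs and disjoint S sets -> combined distance = 1/11."""
    t = _pair_table((150, 152), (150, 152), {"S1", "S2"}, {"S3", "S4"})
    D = combined_matrix(t)
    assert D["x", "y"] == pytest.approx(1 / 11)
    assert D.metric_tag.startswith("combined_bruvo_jaccard")


def test_combined_matrix_clones_and_bounds(panel):
    table, truth = panel
    D = combined_matrix(table)
    assert np.all(D.values >= 0) and np.all(D.values <= 1 + 1e-12)
    assert np.allclose(D.values, D.values.T)
    # combined distance 0 occurs exactly between exact clones
    ids = D.ids
    exact = {
        frozenset({c, s})
        for c, s in truth.clone_map.items()
        if table.accessions[ids.index(c)].ssr_alleles
        == table.accessions[ids.index(s)].ssr_alleles
    }
    zeros = {
        frozenset({ids[i], ids[j]})
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
        if D.values[i, j] == 0.0
    }
    for pair in exact:
        assert pair in zeros
    # zero-distance pairs are all clone-related (same ssr cells + same S set)
    for pair in zeros:
        a, b = sorted(pair)
        ga = table.accessions[ids.index(a)]
        gb = table.accessions[ids.index(b)]
        assert ga.ssr_alleles == gb.ssr_alleles and ga.s_alleles == gb.s_alleles


def test_combined_matrix_missing_locus_averages_over_shared():
    loci = (
        LocusDef("L0", "ssr", repeat_unit=2),
        LocusDef("L1", "ssr", repeat_unit=2),
    )
    accs = (
        AccessionGenotype("x", None, {"L0": (150,), "L1": (150,)}, None),
        AccessionGenotype("y", None, {"L0": (152,)}, None),  # L1 missing
    )
    D = combined_matrix(GenotypeTable(loci=loci, accessions=accs))
    assert D["x", "y"] == pytest.approx(bruvo_allele(150, 152, 2))
    # no shared typed locus -> error
    accs2 = (
        AccessionGenotype("x", None, {"L0": (150,)}, None),
        AccessionGenotype("y", None, {"L1": (152,)}, None),
    )
    with pytest.raises(ValueError, match="no typed locus"):
        combined_matrix(GenotypeTable(loci=loci, accessions=accs2))


def test_nei_distance_boundaries():
    # identical accessions -> 0; fully disjoint -> capped maximum
    t = _pair_table((150, 152), (150, 152), {"S1"}, {"S1"}, n_loci=2)
    N = nei_distance_matrix(t)
    assert N["x", "y"] == pytest.approx(0.0)
    t2 = _pair_table((150,), (160,), {"S1"}, {"S2"}, n_loci=2)
    N2 = nei_distance_matrix(t2)
    assert N2["x", "y"] == NEI_MAX_DISTANCE
    # shared single allele at a monomorphic locus -> D = 0
    loci = (LocusDef("L", "ssr", repeat_unit=2),)
    accs = (
        AccessionGenotype("x", None, {"L": (150,)}, None),
        AccessionGenotype("y", None, {"L": (150,)}, None),
    )
    N3 = nei_distance_matrix(GenotypeTable(loci=loci, accessions=accs))
    assert N3["x", "y"] == 0.0


def test_nei_nonnegative_on_panel(panel):
    table, _ = panel
    N = nei_distance_matrix(table)
    assert np.all(N.values >= 0) and np.all(np.isfinite(N.values))


def test_distance_matrix_container_validation_and_io(tmp_path):
    vals = np.array([[0.0, 1.0], [1.0, 0.0]])
    D = DistanceMatrix(ids=("a", "b"), values=vals, metric_tag="t")
    p = tmp_path / "d.csv"
    D.to_csv(p)
    back = DistanceMatrix.from_csv(p, metric_tag="t")
    assert back.ids == D.ids and np.allclose(back.values, D.values)
    D.to_phylip(tmp_path / "d.phy")
    first = (tmp_path / "d.phy").read_text().splitlines()[0]
    assert first.strip() == "2"
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(ids=("a", "b"), values=np.array([[0.0, 1.0], [0.5, 0.0]]))
    with pytest.raises(ValueError, match="diagonal"):
        DistanceMatrix(ids=("a", "b"), values=np.array([[0.1, 1.0], [1.0, 0.0]]))
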