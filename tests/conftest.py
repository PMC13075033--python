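import pytest

from ployssr import SimConfig, simulate_panel
from ployssr.genotypes import (
    AccessionGenotype,
    GenotypeTable,
    LocusDef,
)


@pytest.fixture(scope="session")
def panel():
    """Default 27-accession, 5-group tetraploid panel with clones/admixture."""
    table, truth = simulate_panel(SimConfig(seed=11))
    return table, truth


@pytest.fixture()
def toy_table():
    """Three accessions, two SSR loci (unit 2) and an S-locus."""
    loci = (
        LocusDef("L1", "ssr", repeat_unit=2, size_range=(100, 140)),
        LocusDef("L2", "ssr", repeat_unit=2),
        LocusDef("S", "s_locus"),
    )
    accs = (
        AccessionGenotype("a1", "G1", {"L1": (100, 102), "L2": (120,)}, frozenset({"S1", "S4"})),
        AccessionGenotype("a2", "G1", {"L1": (100, 104), "L2": (120,)}, frozenset({"S4", "S6"})),
        AccessionGenotype("a3", "G2", {"L1": (110, 112, 114, 116), "L2": (126,)}, frozenset({"S7", "S8"})),
    )
    return GenotypeTable(loci=loci, accessions=accs, ploidy=4)
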