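import numpy as np
import pytest
from hypothesis import settings

from pearid.model import Accession, GermplasmTable, allele_set
from pearid.simulate import default_panel

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_table(rows, loci):
    """Build a GermplasmTable from (id, name, province, {locus: sizes}) rows."""
    accessions = []
    for acc_id, name, prov, genotype in rows:
        accessions.append(
            Accession(
                acc_id, name, prov,
                {l: allele_set(l, sizes) for l, sizes in genotype.items()},
            )
        )
    return GermplasmTable(loci=list(loci), accessions=accessions)


@pytest.fixture
def toy_table():
    """Six accessions: a planted clone pair (A3=A4, different names), a
    homonym pair (A1/A2 both 'Spina'), one triploid (A5) and one accession
    with a missing locus (A6)."""
    loci = ["L1", "L2", "L3"]
    rows = [
        ("A1", "Spina 1 FR", "FR", {"L1": [134, 138], "L2": [200, 204], "L3": [150]}),
        ("A2", "Spina 2 RM", "RM", {"L1": [134, 140], "L2": [200, 206], "L3": [152]}),
        ("A3", "Borina FR", "FR", {"L1": [134, 138], "L2": [202, 206], "L3": [150, 154]}),
        ("A4", "Camella RM", "RM", {"L1": [134, 138], "L2": [202, 206], "L3": [150, 154]}),
        ("A5", "Verdona VT", "VT", {"L1": [134, 138, 142], "L2": [200, 204, 208], "L3": [150]}),
        ("A6", "Lunetta LT", "LT", {"L1": [], "L2": [200], "L3": [150, 152]}),
    ]
    return make_table(rows, loci)


@pytest.fixture(scope="session")
def panel311():
    """The default study-scale synthetic panel (311 accessions, 9 loci)."""
    table, truth, config = default_panel(1)
    return table, truth, config


@pytest.fixture(scope="session")
def small_panel():
    """A small error-free panel with planted clone and homonym structure."""
    table, truth, config = default_panel(
        7,
        n_accessions=60,
        missing_rate=0.0,
        clone_groups=((2, "alias"), (3, "same_name"), (2, "alias")),
        homonym_groups=(("Spina", 2),),
    )
    return table, truth, config
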