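import numpy as np
import pytest

from nuclink.presets import enumerate_precursor_adducts, get_preset
from nuclink.seqdb import ProteinEntry, build_peptide_db, make_decoys
from nuclink.search import build_candidate_index
from nuclink.simdata import random_proteins


@pytest.fixture(scope="session")
def rna_uv():
    return get_preset("RNA-UV")


@pytest.fixture(scope="session")
def rna_nm():
    return get_preset("RNA-NM")


@pytest.fixture(scope="session")
def rna_fa():
    return get_preset("RNA-FA")


@pytest.fixture(scope="session")
def toy_proteins():
    """Ten random 120-residue proteins with regular tryptic sites."""
    return random_proteins(10, 120, seed=1)


@pytest.fixture(scope="session")
def uv_index(rna_uv, toy_proteins):
    peptides = build_peptide_db(make_decoys(toy_proteins))
    adducts = enumerate_precursor_adducts(rna_uv, 1)
    return build_candidate_index(peptides, rna_uv, adducts)
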