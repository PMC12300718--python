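import numpy as np
import pytest

from ttrqsar.descriptors import ELEMENT_PROPERTIES, MolecularGraph


#: (notation 1, notation 2) pairs writing the same molecule two ways.
SMILES_PAIRS = [
    ("OC(=O)C(F)(F)F", "C(F)(F)(F)C(O)=O"),
    ("FC(F)(F)C(F)(F)C(=O)O", "OC(=O)C(F)(F)C(F)(F)F"),
    ("CCO", "OCC"),
    ("c1ccccc1", "C1=CC=CC=C1"),
    ("CC(=O)Oc1ccccc1C(=O)O", "OC(=O)c1ccccc1OC(C)=O"),
    ("FC(F)(F)S(=O)(=O)O", "OS(=O)(=O)C(F)(F)F"),
    ("NCCO", "OCCN"),
    ("ClC(Cl)(Cl)Cl", "C(Cl)(Cl)(Cl)Cl"),
    ("CC#N", "N#CC"),
    ("O=C=O", "C(=O)=O"),
    ("FC(F)=C(F)F", "C(F)(F)=C(F)F"),
    ("CSC", "S(C)C"),
    ("OCC(F)(F)C(F)(F)F", "FC(F)(C(F)(F)F)CO"),
    ("NC(=O)C(F)(F)F", "FC(F)(F)C(N)=O"),
    ("Ic1ccccc1", "c1ccc(I)cc1"),
    ("CC(C)C", "C(C)(C)C"),
    ("OC(=O)CC(=O)O", "C(C(=O)O)C(=O)O"),
    ("FC(F)(F)C(F)(F)I", "IC(F)(F)C(F)(F)F"),
    ("CCS(=O)(=O)N", "NS(=O)(=O)CC"),
    ("Oc1ccccc1", "c1ccc(O)cc1"),
    ("FC(F)(F)OC(F)(F)C(=O)O", "OC(=O)C(F)(F)OC(F)(F)F"),
]

PFOA_SMILES = "OC(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F"


@pytest.fixture(scope="session")
def pfoa_smiles():
    return PFOA_SMILES


@pytest.fixture(scope="session")
def smiles_pairs():
    return SMILES_PAIRS


def random_molecular_graph(rng, n_max=7, connected=True) -> MolecularGraph:
    """Random connected graph with chemical-ish elements and bond orders."""
    elements = list(ELEMENT_PROPERTIES)
    n = int(rng.integers(2, n_max + 1))
    # random spanning tree keeps it connected, then extra edges
    order_pool = [1.0, 1.5, 2.0, 3.0]
    bonds = []
    for i in range(1, n):
        j = int(rng.integers(0, i))
        bonds.append((j, i, float(rng.choice(order_pool))))
    extra = int(rng.integers(0, n))
    for _ in range(extra):
        i, j = rng.integers(0, n, size=2)
        if i != j and not any({a, b} == {int(i), int(j)} for a, b, _ in bonds):
            bonds.append((int(min(i, j)), int(max(i, j)), float(rng.choice(order_pool))))
    els = [elements[int(k)] for k in rng.integers(0, len(elements), size=n)]
    return MolecularGraph(els, bonds)
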