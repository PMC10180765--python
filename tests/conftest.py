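"""Shared fixtures and independent oracles.

The isomorphism oracle is networkx VF2 over the attributed graph — it shares
no code with the engine's canonicalizer, so round-trip and canonicalization
checks are genuinely dual-route.
"""

from __future__ import annotations

import random

import networkx as nx
import pytest

from rxnaug.smiles_engine import MolGraph, parse

# small molecules (<= 8 heavy atoms) covering chains, branches, rings,
# heteroatoms, charges, isotopes, multi-bond orders and aromatics
FIXTURE_SMILES = [
    "C",
    "CC",
    "CCO",
    "OCC",
    "C(C)O",
    "CC(C)C",
    "CC(=O)O",
    "CC(=O)Cl",
    "C1CC1",
    "C1CCC1",
    "C1CCCCC1",
    "C1CC1CO",
    "CC(C)(C)C",
    "N#CC",
    "C=CC=C",
    "OC1CC1",
    "ClCCBr",
    "CSC",
    "NCC(=O)O",
    "c1ccccc1",
    "c1ccncc1",
    "[NH4+]",
    "[O-]CC",
    "[13C]C",
    "CC.O",
]

# subset safe for strict-valence and exhaustive-enumeration work
ENUMERABLE_SMILES = [s for s in FIXTURE_SMILES if "." not in s]


def mol_to_nx(mol: MolGraph) -> nx.Graph:
    g = nx.Graph()
    for atom in mol.atoms:
        g.add_node(atom.index, element=atom.element, aromatic=atom.aromatic,
                   charge=atom.formal_charge, isotope=atom.isotope,
                   h=atom.total_h, chirality=atom.chirality)
    for bond in mol.bonds:
        g.add_edge(bond.a, bond.b, order=bond.order)
    return g


def isomorphic(a: MolGraph, b: MolGraph) -> bool:
    """VF2 matching on full attribute equality (independent oracle)."""
    return nx.is_isomorphic(
        mol_to_nx(a), mol_to_nx(b),
        node_match=lambda x, y: x == y,
        edge_match=lambda x, y: x == y)


def smiles_isomorphic(s1: str, s2: str) -> bool:
    """Component-wise isomorphism of two (possibly multi-component) SMILES."""
    c1 = parse(s1)
    c2 = parse(s2)
    if len(c1) != len(c2):
        return False
    unused = list(range(len(c2)))
    for comp in c1:
        for k in list(unused):
            if isomorphic(comp, c2[k]):
                unused.remove(k)
                break
        else:
            return False
    return True


def relabel(mol: MolGraph, perm: list[int]) -> MolGraph:
    """Rebuild ``mol`` with atom ``i`` moved to position ``perm[i]``."""
    g = MolGraph()
    inverse = [0] * len(perm)
    for old, new in enumerate(perm):
        inverse[new] = old
    for new in range(mol.n_atoms):
        g.add_atom(mol.atoms[inverse[new]].copy())
    for bond in mol.bonds:
        g.add_bond(perm[bond.a], perm[bond.b], bond.order,
                   direction=bond.direction,
                   dir_from=perm[bond.dir_from] if bond.dir_from is not None else None)
    return g


@pytest.fixture
def rng():
    return random.Random(20240901)


@pytest.fixture(params=FIXTURE_SMILES)
def fixture_smiles(request):
    return request.param
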