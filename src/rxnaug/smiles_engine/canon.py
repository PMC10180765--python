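"""Canonical atom ranking and canonical SMILES.

Ranks are computed by iterative partition refinement on atom invariants
(element, aromaticity, charge, isotope, attached-H count, degree, bond-order
multiset), refined with neighbor ranks until stable.  Ties are broken by
artificial symmetry breaking: the lowest-ranked non-singleton cell is split by
promoting each member in turn, the refinement re-run, and the candidate whose
fully-resolved ranking writes the lexicographically least SMILES wins.  The
result therefore depends only on the isomorphism class of the attributed
graph, never on input atom order.

Stereo annotations ('@', '@@', '/', '\\\\') are carried through as opaque
attributes and compared verbatim; no parity recomputation is attempted.
"""

from __future__ import annotations

from .graph import BOND_ORDER_VALUE, MolGraph
from .parser import parse
from .writer import write

__all__ = ["canonical_ranks", "canonical", "canonical_components"]


def _initial_invariants(mol: MolGraph) -> list[tuple]:
    invs = []
    for atom in mol.atoms:
        orders = sorted(b.order for b in mol.bonds_of(atom.index))
        invs.append((
            atom.element,
            atom.aromatic,
            atom.formal_charge,
            atom.isotope or 0,
            atom.chirality or "",
            atom.total_h,
            mol.degree(atom.index),
            tuple(orders),
        ))
    return invs


def _dense_ranks(keys: list) -> list[int]:
    order = sorted(set(keys))
    lookup = {k: r for r, k in enumerate(order)}
    return [lookup[k] for k in keys]


def _refine(mol: MolGraph, ranks: list[int]) -> list[int]:
    """Iterate neighborhood refinement until the partition stabilizes."""
    n = mol.n_atoms
    while True:
        keys = []
        for i in range(n):
            nbr_key = sorted(
                (BOND_ORDER_VALUE[b.order], ranks[b.other(i)])
                for b in mol.bonds_of(i))
            keys.append((ranks[i], tuple(nbr_key)))
        new = _dense_ranks(keys)
        if len(set(new)) == len(set(ranks)):
            return new
        ranks = new


def _canonical_string(mol: MolGraph, ranks: list[int]) -> str:
    """Write with fully discrete ranks: start at rank 0, neighbors by rank."""
    start = ranks.index(min(ranks))
    return write(mol, start, lambda _i, nbrs: sorted(nbrs, key=lambda j: ranks[j]))


def _resolve(mol: MolGraph, ranks: list[int]) -> tuple[str, list[int]]:
    ranks = _refine(mol, ranks)
    n = mol.n_atoms
    if len(set(ranks)) == n:
        return _canonical_string(mol, ranks), ranks
    # lowest-ranked tied cell
    counts: dict[int, list[int]] = {}
    for i, r in enumerate(ranks):
        counts.setdefault(r, []).append(i)
    cell_rank = min(r for r, members in counts.items() if len(members) > 1)
    best: tuple[str, list[int]] | None = None
    for candidate in counts[cell_rank]:
        # promote: give candidate a rank strictly below its cell mates
        trial = [2 * r for r in ranks]
        trial[candidate] -= 1
        result = _resolve(mol, trial)
        if best is None or result[0] < best[0]:
            best = result
    assert best is not None
    return best


def canonical_ranks(mol: MolGraph) -> list[int]:
    """A canonical permutation of atom indices (rank per atom).

    Invariant to input atom order: relabeling the graph and re-ranking yields
    ranks that induce the same canonical SMILES.
    """
    if mol.n_atoms == 0:
        return []
    _, ranks = _resolve(mol, _dense_ranks(_initial_invariants(mol)))
    return ranks


def canonical_component(mol: MolGraph) -> str:
    """Canonical SMILES of one connected component."""
    if mol.n_atoms == 0:
        raise ValueError("empty graph")
    s, _ = _resolve(mol, _dense_ranks(_initial_invariants(mol)))
    return s


def canonical_components(smiles: str) -> list[str]:
    """Canonical SMILES of each '.'-component, sorted lexicographically."""
    return sorted(canonical_component(c) for c in parse(smiles))


def canonical(smiles: str) -> str:
    """Unique representative string for the molecule(s) in ``smiles``.

    Components are canonicalized individually, sorted, and joined with '.';
    two inputs map to the same output iff their parses are isomorphic
    attributed graphs.  Idempotent.
    """
    return ".".join(canonical_components(smiles))
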