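"""Attributed molecular graph model underlying the SMILES engine.

A :class:`MolGraph` is a simple undirected graph of :class:`Atom` nodes and
:class:`Bond` edges.  It is the parse target of :mod:`rxnaug.smiles_engine.parser`
and the source for the writer, the canonicalizer and random enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Optional

__all__ = [
    "Atom",
    "Bond",
    "MolGraph",
    "ORGANIC_SUBSET",
    "SUPPORTED_ELEMENTS",
    "AROMATIC_ELEMENTS",
    "BOND_ORDER_VALUE",
    "DEFAULT_VALENCES",
]

#: elements writable without brackets (implicit-H rules apply)
ORGANIC_SUBSET = {"B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I"}

#: elements accepted anywhere (brackets may also carry H)
SUPPORTED_ELEMENTS = ORGANIC_SUBSET | {"H"}

#: elements that may carry the aromatic flag (written lowercase)
AROMATIC_ELEMENTS = {"B", "C", "N", "O", "P", "S"}

BOND_ORDER_VALUE = {"single": 1.0, "double": 2.0, "triple": 3.0, "aromatic": 1.5}

#: standard implicit-hydrogen valence sets
DEFAULT_VALENCES = {
    "B": (3,),
    "C": (4,),
    "N": (3, 5),
    "O": (2,),
    "P": (3, 5),
    "S": (2, 4, 6),
    "F": (1,),
    "Cl": (1,),
    "Br": (1,),
    "I": (1,),
    "H": (1,),
}


@dataclass
class Atom:
    """A single atom.

    ``explicit_h``/``isotope``/``formal_charge``/``chirality`` may only be set
    on bracket atoms; ``implicit_h`` is derived by the parser for organic-subset
    atoms (``None`` until computed).
    """

    element: str
    aromatic: bool = False
    formal_charge: int = 0
    explicit_h: Optional[int] = None
    isotope: Optional[int] = None
    bracket: bool = False
    chirality: Optional[str] = None
    index: int = -1
    implicit_h: Optional[int] = None

    @property
    def total_h(self) -> int:
        """Hydrogen count attached to this atom (explicit for bracket atoms)."""
        if self.bracket:
            return self.explicit_h or 0
        return self.implicit_h or 0

    def copy(self) -> "Atom":
        return replace(self)


@dataclass
class Bond:
    """An undirected edge. ``direction`` ('/' or '\\\\') is an opaque annotation
    oriented from ``dir_from`` toward the other endpoint."""

    a: int
    b: int
    order: str = "single"
    direction: Optional[str] = None
    dir_from: Optional[int] = None

    def other(self, idx: int) -> int:
        return self.b if idx == self.a else self.a

    @property
    def value(self) -> float:
        return BOND_ORDER_VALUE[self.order]

    def copy(self) -> "Bond":
        return replace(self)


class MolGraph:
    """Simple undirected attributed graph; one connected component."""

    def __init__(self) -> None:
        self.atoms: list[Atom] = []
        self.bonds: list[Bond] = []
        self._adj: dict[int, list[Bond]] = {}

    # -- construction -------------------------------------------------
    def add_atom(self, atom: Atom) -> int:
        atom.index = len(self.atoms)
        self.atoms.append(atom)
        self._adj[atom.index] = []
        return atom.index

    def add_bond(self, a: int, b: int, order: str = "single", **kw) -> Bond:
        if a == b:
            raise ValueError("self-bond not allowed")
        if self.bond_between(a, b) is not None:
            raise ValueError(f"duplicate bond {a}-{b}")
        bond = Bond(a, b, order, **kw)
        self.bonds.append(bond)
        self._adj[a].append(bond)
        self._adj[b].append(bond)
        return bond

    def remove_atom(self, idx: int) -> None:
        """Delete an atom and its bonds; remaining atoms are re-indexed."""
        self.bonds = [b for b in self.bonds if idx not in (b.a, b.b)]
        del self.atoms[idx]
        remap = {}
        for new, atom in enumerate(self.atoms):
            remap[atom.index] = new
            atom.index = new
        for bond in self.bonds:
            bond.a = remap[bond.a]
            bond.b = remap[bond.b]
            if bond.dir_from is not None:
                bond.dir_from = remap.get(bond.dir_from)
        self._rebuild_adj()

    def _rebuild_adj(self) -> None:
        self._adj = {a.index: [] for a in self.atoms}
        for bond in self.bonds:
            self._adj[bond.a].append(bond)
            self._adj[bond.b].append(bond)

    # -- queries ------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, idx: int) -> list[int]:
        return [b.other(idx) for b in self._adj[idx]]

    def bonds_of(self, idx: int) -> list[Bond]:
        return list(self._adj[idx])

    def bond_between(self, a: int, b: int) -> Optional[Bond]:
        for bond in self._adj.get(a, ()):
            if bond.other(a) == b:
                return bond
        return None

    def degree(self, idx: int) -> int:
        return len(self._adj[idx])

    def bond_value_sum(self, idx: int) -> float:
        return sum(b.value for b in self._adj[idx])

    def is_connected(self) -> bool:
        if not self.atoms:
            return True
        seen = {0}
        stack = [0]
        while stack:
            for nbr in self.neighbors(stack.pop()):
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        return len(seen) == self.n_atoms

    def copy(self) -> "MolGraph":
        g = MolGraph()
        for atom in self.atoms:
            g.add_atom(atom.copy())
        for bond in self.bonds:
            g.add_bond(bond.a, bond.b, bond.order,
                       direction=bond.direction, dir_from=bond.dir_from)
        return g

    def components(self) -> list["MolGraph"]:
        """Connected components as fresh re-indexed graphs."""
        unseen = set(range(self.n_atoms))
        out = []
        while unseen:
            root = min(unseen)
            comp = {root}
            stack = [root]
            while stack:
                for nbr in self.neighbors(stack.pop()):
                    if nbr not in comp:
                        comp.add(nbr)
                        stack.append(nbr)
            unseen -= comp
            order = sorted(comp)
            remap = {old: new for new, old in enumerate(order)}
            g = MolGraph()
            for old in order:
                g.add_atom(self.atoms[old].copy())
            for bond in self.bonds:
                if bond.a in comp:
                    g.add_bond(remap[bond.a], remap[bond.b], bond.order,
                               direction=bond.direction,
                               dir_from=remap.get(bond.dir_from)
                               if bond.dir_from is not None else None)
            out.append(g)
        return out

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    def __repr__(self) -> str:
        return f"MolGraph(n_atoms={self.n_atoms}, n_bonds={len(self.bonds)})"


def compute_implicit_h(mol: MolGraph) -> None:
    """Fill ``implicit_h`` for organic-subset atoms using default valences.

    For aromatic atoms the aromatic bond contributes 1.5; the hydrogen count
    is ``v - ceil(sum)`` for the smallest allowed valence ``v >= ceil(sum)``,
    zero when the bond sum exceeds every allowed valence.
    """
    import math

    for atom in mol.atoms:
        if atom.bracket:
            atom.implicit_h = None
            continue
        need = math.ceil(mol.bond_value_sum(atom.index) - 1e-9)
        for v in DEFAULT_VALENCES[atom.element]:
            if v >= need:
                atom.implicit_h = v - need
                break
        else:
            atom.implicit_h = 0


def valence_errors(mol: MolGraph) -> list[tuple[int, str]]:
    """Strict-valence violations: (atom index, message) pairs.

    Aromatic atoms are skipped (no kekulization is attempted).  Allowed
    valences are shifted by the formal charge for bracket atoms.
    """
    import math

    errors = []
    for atom in mol.atoms:
        if atom.aromatic:
            continue
        total = math.ceil(mol.bond_value_sum(atom.index) - 1e-9) + atom.total_h
        allowed = DEFAULT_VALENCES[atom.element]
        if atom.bracket:
            allowed = tuple(v + atom.formal_charge for v in allowed)
        if total not in allowed:
            errors.append(
                (atom.index,
                 f"atom {atom.index} ({atom.element}) valence {total} "
                 f"not in {allowed}"))
    return errors
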