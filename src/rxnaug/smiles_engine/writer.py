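"""SMILES writer: deterministic, randomized and exhaustive graph traversals.

The writer performs a depth-first traversal from a chosen start atom.  The
order in which unvisited neighbors are expanded is pluggable, which is what
turns one molecular graph into many equivalent SMILES strings: different
start atoms and branch orders yield different (all valid) writings.
"""

from __future__ import annotations

import heapq
import random
from itertools import permutations
from typing import Callable, Iterator, Optional, Sequence

from .graph import Atom, Bond, MolGraph

__all__ = ["write", "random_smiles", "enumerate_smiles", "enumerate_component"]

NeighborOrder = Callable[[int, Sequence[int]], Sequence[int]]


def _atom_token(atom: Atom) -> str:
    needs_bracket = (atom.bracket or atom.formal_charge != 0
                     or atom.isotope is not None or atom.chirality is not None
                     or atom.explicit_h is not None)
    symbol = atom.element.lower() if atom.aromatic else atom.element
    if not needs_bracket:
        return symbol
    parts = ["["]
    if atom.isotope is not None:
        parts.append(str(atom.isotope))
    parts.append(symbol)
    if atom.chirality:
        parts.append(atom.chirality)
    h = atom.explicit_h or 0
    if h == 1:
        parts.append("H")
    elif h > 1:
        parts.append(f"H{h}")
    c = atom.formal_charge
    if c == 1:
        parts.append("+")
    elif c == -1:
        parts.append("-")
    elif c > 1:
        parts.append(f"+{c}")
    elif c < -1:
        parts.append(str(c))
    parts.append("]")
    return "".join(parts)


def _bond_token(bond: Bond, from_atom: int, atoms: list[Atom]) -> str:
    """Symbol emitted when traversing ``bond`` out of ``from_atom``."""
    if bond.direction is not None:
        return bond.direction if bond.dir_from == from_atom else (
            "\\" if bond.direction == "/" else "/")
    a, b = atoms[bond.a], atoms[bond.b]
    if bond.order == "single":
        return "-" if (a.aromatic and b.aromatic) else ""
    if bond.order == "aromatic":
        return "" if (a.aromatic and b.aromatic) else ":"
    return {"double": "=", "triple": "#"}[bond.order]


def _ring_label(digit: int) -> str:
    return str(digit) if digit < 10 else f"%{digit:02d}"


def write(mol: MolGraph, start_atom: int = 0,
          neighbor_order: Optional[NeighborOrder] = None) -> str:
    """Write one connected :class:`MolGraph` as a SMILES string.

    ``neighbor_order`` maps ``(atom index, unvisited/ring-partner candidates)``
    to an ordering of those candidates; the default is ascending atom index.
    Ring-closure digits are allocated smallest-free-first and reused once
    closed; labels >= 10 use the ``%nn`` form.
    """
    if not 0 <= start_atom < mol.n_atoms:
        raise IndexError(f"start_atom {start_atom} out of range")
    if neighbor_order is None:
        neighbor_order = lambda _i, nbrs: sorted(nbrs)

    # pass 1: DFS establishing tree children and ring bonds, with the
    # neighbor ordering frozen so pass 2 replays it exactly.
    children: dict[int, list[int]] = {}
    ring_open: dict[int, list[tuple[int, Bond]]] = {}   # open atom -> closures
    ring_close: dict[int, list[tuple[int, Bond]]] = {}  # close atom -> closures
    visited = set()
    used_bonds: set[int] = set()
    order_of: dict[int, list[int]] = {}

    def dfs(at: int, parent_bond: Optional[Bond]) -> None:
        visited.add(at)
        nbrs = [b.other(at) for b in mol.bonds_of(at) if b is not parent_bond]
        ordered = list(neighbor_order(at, nbrs))
        if sorted(ordered) != sorted(nbrs):
            raise ValueError("neighbor_order must permute the candidates")
        order_of[at] = ordered
        children[at] = []
        for nbr in ordered:
            bond = mol.bond_between(at, nbr)
            bid = id(bond)
            if bid in used_bonds:
                continue
            if nbr in visited:
                used_bonds.add(bid)
                ring_open.setdefault(nbr, []).append((at, bond))
                ring_close.setdefault(at, []).append((nbr, bond))
            else:
                used_bonds.add(bid)
                children[at].append(nbr)
                dfs(nbr, bond)

    prev_limit = None
    if mol.n_atoms > 900:
        import sys
        prev_limit = sys.getrecursionlimit()
        sys.setrecursionlimit(max(prev_limit, mol.n_atoms * 4 + 100))
    try:
        dfs(start_atom, None)
    finally:
        if prev_limit is not None:
            import sys
            sys.setrecursionlimit(prev_limit)
    if len(visited) != mol.n_atoms:
        raise ValueError("graph is not connected")

    # pass 2: emit tokens in traversal order, allocating ring digits.
    free: list[int] = []
    next_digit = [1]
    digit_of: dict[int, int] = {}  # id(bond) -> digit
    out: list[str] = []

    def alloc() -> int:
        if free:
            return heapq.heappop(free)
        d = next_digit[0]
        next_digit[0] += 1
        return d

    def emit(at: int, parent: Optional[int], parent_bond: Optional[Bond]) -> None:
        if parent_bond is not None:
            out.append(_bond_token(parent_bond, parent, mol.atoms))
        out.append(_atom_token(mol.atoms[at]))
        # closures first (digits already allocated at the open end),
        # then new openings
        for partner, bond in ring_close.get(at, ()):
            d = digit_of.pop(id(bond))
            heapq.heappush(free, d)
            out.append(_bond_token(bond, at, mol.atoms) + _ring_label(d))
        for _partner, bond in ring_open.get(at, ()):
            d = alloc()
            digit_of[id(bond)] = d
            out.append(_ring_label(d))
        kids = children[at]
        for i, kid in enumerate(kids):
            bond = mol.bond_between(at, kid)
            last = i == len(kids) - 1
            if not last:
                out.append("(")
            emit(kid, at, bond)
            if not last:
                out.append(")")

    prev_limit = None
    if mol.n_atoms > 900:
        import sys
        prev_limit = sys.getrecursionlimit()
        sys.setrecursionlimit(max(prev_limit, mol.n_atoms * 6 + 100))
    try:
        emit(start_atom, None, None)
    finally:
        if prev_limit is not None:
            import sys
            sys.setrecursionlimit(prev_limit)
    return "".join(out)


def random_smiles(mol: MolGraph, seed) -> str:
    """An equivalent SMILES with uniformly random start atom and branch order.

    ``seed`` may be an int or a :class:`random.Random`; identical seeds give
    identical strings.
    """
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    start = rng.randrange(mol.n_atoms)

    def shuffle_order(_i: int, nbrs: Sequence[int]) -> Sequence[int]:
        out = list(nbrs)
        rng.shuffle(out)
        return out

    return write(mol, start, shuffle_order)


def enumerate_component(mol: MolGraph, max_strings: Optional[int] = None) -> Iterator[str]:
    """Yield every SMILES writable for ``mol`` over all (start, branch order)
    choices.  Output may contain duplicates when different traversals coincide
    textually.  Intended for small graphs (exponential in branching)."""
    count = 0
    for start in range(mol.n_atoms):
        for s in _enumerate_from(mol, start):
            yield s
            count += 1
            if max_strings is not None and count >= max_strings:
                return


def _enumerate_from(mol: MolGraph, start: int) -> Iterator[str]:
    # Choice points are the per-atom neighbor orderings encountered in DFS
    # order.  Each write replays a prefix of choices and records the radix
    # (number of permutations) at every step; a mixed-radix odometer then
    # walks every combination.  Later radixes may depend on earlier choices,
    # which is why they are re-recorded on every pass.
    choices: list[int] = []
    while True:
        step = [0]
        radixes: list[int] = []

        def order(_i: int, nbrs: Sequence[int]) -> Sequence[int]:
            k = step[0]
            step[0] += 1
            perms = sorted(permutations(sorted(nbrs)))
            radixes.append(len(perms))
            if k >= len(choices):
                choices.append(0)
            return list(perms[choices[k]])

        yield write(mol, start, order)
        pos = len(choices) - 1
        while pos >= 0 and choices[pos] + 1 >= radixes[pos]:
            pos -= 1
        if pos < 0:
            return
        choices[pos] += 1
        del choices[pos + 1:]


def enumerate_smiles(mol: MolGraph, max_strings: Optional[int] = None) -> set[str]:
    """Set of all distinct SMILES strings writable for ``mol``."""
    out = set()
    for s in enumerate_component(mol, max_strings):
        out.add(s)
    return out
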