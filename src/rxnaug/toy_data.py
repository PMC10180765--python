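"""Synthetic reaction data with realistic benchmark structure.

Generates random small molecules, applies rule-based reaction templates
(nucleophilic substitution, acylation, ether deprotection analogues spanning
three reaction classes), and assembles class-imbalanced datasets so the full
augment/normalize/evaluate pipeline can be exercised without any external
download.  A nearest-neighbor retrieval predictor stands in for a trained
sequence model so that ranked-beam evaluation has something to score.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .evaluation import BeamSet
from .normalization import char_normalize
from .reaction_io import ReactionRecord
from .smiles_engine import (
    Atom,
    MolGraph,
    canonical_component,
    compute_implicit_h,
    parse,
)

__all__ = [
    "ToyTemplate",
    "ToyDatasetConfig",
    "TEMPLATES",
    "gen_molecule",
    "apply_template",
    "gen_dataset",
    "retrieval_predict",
    "retrieval_predict_batch",
    "token_edit_distance",
]

# free-valence budget used by the generator (single bonds only)
_CAPACITY = {"C": 4, "N": 3, "O": 2, "S": 2, "F": 1, "Cl": 1, "Br": 1}
_ELEMENTS = ("C", "N", "O", "S", "F", "Cl", "Br")
_WEIGHTS = (0.58, 0.12, 0.14, 0.04, 0.04, 0.04, 0.04)


def gen_molecule(size: int, seed, elements: Sequence[str] = _ELEMENTS,
                 weights: Sequence[float] = _WEIGHTS,
                 ring_prob: float = 0.25) -> MolGraph:
    """Random connected, acyclic-or-monocyclic, strict-valence-valid molecule.

    Atoms are drawn from ``elements`` and attached one at a time to a random
    atom with free valence; an optional single ring (size >= 3) is closed at
    the end.  No aromatics, no charges, no stereo.  Deterministic per seed.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    mol = MolGraph()
    free: dict[int, int] = {}

    def place(element: str, attach_to: Optional[int]) -> int:
        idx = mol.add_atom(Atom(element=element))
        free[idx] = _CAPACITY[element]
        if attach_to is not None:
            mol.add_bond(attach_to, idx)
            free[attach_to] -= 1
            free[idx] -= 1
        return idx

    first = "C" if size > 1 else rng.choices(elements, weights)[0]
    place(first, None)
    for _ in range(size - 1):
        anchors = [i for i, f in free.items() if f > 0]
        if not anchors:
            raise ValueError(f"size {size} unsatisfiable: no free valence left")
        anchor = rng.choice(anchors)
        element = rng.choices(elements, weights)[0]
        # keep the graph extendable: terminal atoms only when capacity remains
        remaining = sum(f for f in free.values()) - 1
        if remaining + _CAPACITY[element] - 1 < 1 and len(mol.atoms) + 1 < size:
            element = "C"
        place(element, anchor)

    if size >= 3 and rng.random() < ring_prob:
        open_atoms = [i for i, f in free.items() if f > 0]
        rng.shuffle(open_atoms)
        for a in open_atoms:
            partners = [b for b in open_atoms
                        if b != a and mol.bond_between(a, b) is None
                        and _tree_distance(mol, a, b) >= 2]
            if partners:
                mol.add_bond(a, rng.choice(partners))
                break
    compute_implicit_h(mol)
    return mol


def _tree_distance(mol: MolGraph, a: int, b: int) -> int:
    from collections import deque

    seen = {a: 0}
    q = deque([a])
    while q:
        cur = q.popleft()
        if cur == b:
            return seen[cur]
        for nbr in mol.neighbors(cur):
            if nbr not in seen:
                seen[nbr] = seen[cur] + 1
                q.append(nbr)
    return -1


def _free_valence(mol: MolGraph, idx: int) -> float:
    atom = mol.atoms[idx]
    return _CAPACITY[atom.element] - mol.bond_value_sum(idx)


def _merge(dst: MolGraph, src: MolGraph) -> dict[int, int]:
    """Copy ``src`` atoms/bonds into ``dst``; returns old->new index map."""
    remap = {}
    for atom in src.atoms:
        remap[atom.index] = dst.add_atom(atom.copy())
    for bond in src.bonds:
        dst.add_bond(remap[bond.a], remap[bond.b], bond.order)
    return remap


# --------------------------------------------------------------------------
# reaction templates


@dataclass
class ToyTemplate:
    """A named rewrite rule: ``matcher`` locates the reacting sites on parsed
    reactant graphs (None when the template does not apply), ``rewriter``
    performs the graph edit and returns product components (main product
    first), ``builder`` constructs random reactant sets that are guaranteed
    to match."""

    name: str
    rx_class: str
    n_reactants: int
    matcher: Callable[[list[MolGraph]], Optional[tuple]]
    rewriter: Callable[[list[MolGraph], tuple], list[MolGraph]]
    builder: Callable[[random.Random, tuple[int, int]], list[str]]


class TemplateMatchError(ValueError):
    """Reactants do not contain the template's functional groups."""


def _find_hydroxyl(mol: MolGraph) -> Optional[int]:
    """Index of an -OH oxygen: non-aromatic O, one single bond to C, >= 1 H."""
    for atom in mol.atoms:
        if (atom.element == "O" and not atom.aromatic and not atom.bracket
                and mol.degree(atom.index) == 1 and atom.total_h >= 1):
            bond = mol.bonds_of(atom.index)[0]
            nbr = mol.atoms[bond.other(atom.index)]
            if bond.order == "single" and nbr.element == "C":
                return atom.index
    return None


def _find_acyl_halide(mol: MolGraph) -> Optional[tuple[int, int]]:
    """(carbonyl C, halogen) of a C(=O)Cl / C(=O)Br motif."""
    for atom in mol.atoms:
        if atom.element != "C" or atom.aromatic:
            continue
        has_carbonyl = any(
            b.order == "double" and mol.atoms[b.other(atom.index)].element == "O"
            for b in mol.bonds_of(atom.index))
        halogen = next(
            (b.other(atom.index) for b in mol.bonds_of(atom.index)
             if b.order == "single"
             and mol.atoms[b.other(atom.index)].element in ("Cl", "Br")),
            None)
        if has_carbonyl and halogen is not None:
            return atom.index, halogen
    return None


def _find_alkyl_halide(mol: MolGraph) -> Optional[tuple[int, int]]:
    """(carbon, halogen) of a C-Br / C-Cl with a plain sp3 carbon."""
    for atom in mol.atoms:
        if atom.element not in ("Br", "Cl") or mol.degree(atom.index) != 1:
            continue
        bond = mol.bonds_of(atom.index)[0]
        c = bond.other(atom.index)
        c_atom = mol.atoms[c]
        if (bond.order == "single" and c_atom.element == "C"
                and not c_atom.aromatic
                and not any(b.order == "double" for b in mol.bonds_of(c))):
            return c, atom.index
    return None


def _find_amine(mol: MolGraph) -> Optional[int]:
    """Index of an N with at least one H and spare valence (not amide-like)."""
    for atom in mol.atoms:
        if (atom.element == "N" and not atom.aromatic and not atom.bracket
                and atom.total_h >= 1 and _free_valence(mol, atom.index) >= 1
                and all(b.order == "single" for b in mol.bonds_of(atom.index))):
            return atom.index
    return None


def _find_methyl_ether(mol: MolGraph) -> Optional[tuple[int, int]]:
    """(ether O, methyl C) of an R-O-CH3 motif."""
    for atom in mol.atoms:
        if atom.element != "O" or atom.aromatic or mol.degree(atom.index) != 2:
            continue
        if not all(b.order == "single" for b in mol.bonds_of(atom.index)):
            continue
        for b in mol.bonds_of(atom.index):
            c = b.other(atom.index)
            c_atom = mol.atoms[c]
            if (c_atom.element == "C" and mol.degree(c) == 1
                    and c_atom.total_h == 3):
                return atom.index, c
    return None


def _single_atom(element: str) -> MolGraph:
    g = MolGraph()
    g.add_atom(Atom(element=element))
    return g


# -- acylation: R-OH + R'-C(=O)X -> R-O-C(=O)-R' + HX ----------------------

def _match_acylation(mols: list[MolGraph]) -> Optional[tuple]:
    if len(mols) != 2:
        return None
    o = _find_hydroxyl(mols[0])
    acyl = _find_acyl_halide(mols[1])
    if o is None or acyl is None:
        return None
    return (o, *acyl)


def _rewrite_acylation(mols: list[MolGraph], match: tuple) -> list[MolGraph]:
    o_idx, c_idx, x_idx = match
    halogen = mols[1].atoms[x_idx].element
    product = MolGraph()
    m0 = _merge(product, mols[0])
    m1 = _merge(product, mols[1])
    product.remove_atom(m1[x_idx])
    # re-locate the carbonyl C after re-indexing: removal shifts indices
    shift = 1 if m1[c_idx] > m1[x_idx] else 0
    product.add_bond(m0[o_idx], m1[c_idx] - shift)
    compute_implicit_h(product)
    return [product, _single_atom(halogen)]


def _scaffold_with_open_carbon(rng: random.Random, size: int,
                               **gen_kw) -> tuple[MolGraph, list[int]]:
    """A random scaffold guaranteed to expose >= 1 sp3 carbon with free
    valence (regenerates on the rare fully-saturated draw)."""
    while True:
        mol = gen_molecule(size, rng, **gen_kw)
        carbons = [a.index for a in mol.atoms
                   if a.element == "C" and _free_valence(mol, a.index) >= 1
                   and not any(b.order == "double" for b in mol.bonds_of(a.index))]
        if carbons:
            return mol, carbons


def _build_acylation(rng: random.Random, size_range: tuple[int, int]) -> list[str]:
    lo, hi = size_range
    r1, carbons = _scaffold_with_open_carbon(rng, rng.randint(lo, hi))
    o = r1.add_atom(Atom(element="O"))
    r1.add_bond(rng.choice(carbons), o)

    lo2, hi2 = max(lo - 1, 1), max(hi - 2, lo - 1, 1)
    r2, anchors = _scaffold_with_open_carbon(
        rng, rng.randint(lo2, hi2),
        elements=("C", "N", "O"), weights=(0.8, 0.1, 0.1), ring_prob=0.1)
    cc = r2.add_atom(Atom(element="C"))
    r2.add_bond(rng.choice(anchors), cc)
    oo = r2.add_atom(Atom(element="O"))
    r2.add_bond(cc, oo, "double")
    x = r2.add_atom(Atom(element="Cl"))
    r2.add_bond(cc, x)
    compute_implicit_h(r1)
    compute_implicit_h(r2)
    return [canonical_component(r1), canonical_component(r2)]


# -- substitution: R-X + R'-NH -> R-N(R') + HX -----------------------------

def _match_substitution(mols: list[MolGraph]) -> Optional[tuple]:
    if len(mols) != 2:
        return None
    halide = _find_alkyl_halide(mols[0])
    n = _find_amine(mols[1])
    if halide is None or n is None:
        return None
    return (*halide, n)


def _rewrite_substitution(mols: list[MolGraph], match: tuple) -> list[MolGraph]:
    c_idx, x_idx, n_idx = match
    halogen = mols[0].atoms[x_idx].element
    product = MolGraph()
    m0 = _merge(product, mols[0])
    m1 = _merge(product, mols[1])
    product.remove_atom(m0[x_idx])
    shift_c = 1 if m0[c_idx] > m0[x_idx] else 0
    shift_n = 1 if m1[n_idx] > m0[x_idx] else 0
    product.add_bond(m0[c_idx] - shift_c, m1[n_idx] - shift_n)
    compute_implicit_h(product)
    return [product, _single_atom(halogen)]


def _build_substitution(rng: random.Random, size_range: tuple[int, int]) -> list[str]:
    lo, hi = size_range
    r1, carbons = _scaffold_with_open_carbon(
        rng, rng.randint(lo, hi),
        elements=("C", "O"), weights=(0.85, 0.15), ring_prob=0.2)
    x = r1.add_atom(Atom(element=rng.choice(("Br", "Cl"))))
    r1.add_bond(rng.choice(carbons), x)

    r2, anchors = _scaffold_with_open_carbon(
        rng, rng.randint(max(lo - 1, 1), hi),
        elements=("C", "O"), weights=(0.9, 0.1), ring_prob=0.2)
    n = r2.add_atom(Atom(element="N"))
    r2.add_bond(rng.choice(anchors), n)
    compute_implicit_h(r1)
    compute_implicit_h(r2)
    return [canonical_component(r1), canonical_component(r2)]


# -- deprotection: R-O-CH3 -> R-OH + CH4 -----------------------------------

def _match_deprotection(mols: list[MolGraph]) -> Optional[tuple]:
    if len(mols) != 1:
        return None
    return _find_methyl_ether(mols[0])


def _rewrite_deprotection(mols: list[MolGraph], match: tuple) -> list[MolGraph]:
    _o_idx, c_idx = match
    product = mols[0].copy()
    product.remove_atom(c_idx)
    compute_implicit_h(product)
    return [product, _single_atom("C")]


def _build_deprotection(rng: random.Random, size_range: tuple[int, int]) -> list[str]:
    lo, hi = size_range
    r1, anchors = _scaffold_with_open_carbon(
        rng, rng.randint(lo, hi),
        elements=("C", "N", "O"), weights=(0.7, 0.1, 0.2), ring_prob=0.2)
    o = r1.add_atom(Atom(element="O"))
    r1.add_bond(rng.choice(anchors), o)
    me = r1.add_atom(Atom(element="C"))
    r1.add_bond(o, me)
    compute_implicit_h(r1)
    return [canonical_component(r1)]


TEMPLATES: dict[str, ToyTemplate] = {
    "Rx_1": ToyTemplate(
        name="n_alkylation", rx_class="Rx_1", n_reactants=2,
        matcher=_match_substitution, rewriter=_rewrite_substitution,
        builder=_build_substitution),
    "Rx_2": ToyTemplate(
        name="acylation", rx_class="Rx_2", n_reactants=2,
        matcher=_match_acylation, rewriter=_rewrite_acylation,
        builder=_build_acylation),
    "Rx_6": ToyTemplate(
        name="ether_deprotection", rx_class="Rx_6", n_reactants=1,
        matcher=_match_deprotection, rewriter=_rewrite_deprotection,
        builder=_build_deprotection),
}


def apply_template(template: ToyTemplate, reactants: Sequence[str],
                   keep_byproducts: bool = True) -> ReactionRecord:
    """Apply a template to reactant SMILES; raises
    :class:`TemplateMatchError` when the functional groups are absent.

    Products are canonical; the main product comes first, followed by the
    small leaving species unless ``keep_byproducts`` is off.
    """
    mols = [parse(s)[0] for s in reactants]
    match = template.matcher(mols)
    if match is None:
        raise TemplateMatchError(
            f"template {template.name}: no match on {list(reactants)}")
    products = template.rewriter(mols, match)
    product_smiles = [canonical_component(p) for p in products]
    if not keep_byproducts:
        product_smiles = product_smiles[:1]
    rec = ReactionRecord(reactants=list(reactants), products=product_smiles,
                         rx_class=template.rx_class)
    rec.validate()
    return rec


@dataclass
class ToyDatasetConfig:
    """Dataset shape: size, class mix (imbalanced by default, echoing typical
    benchmark skew), molecule sizes, RNG seed."""

    n_reactions: int = 1000
    class_weights: dict[str, float] = field(
        default_factory=lambda: {"Rx_1": 0.55, "Rx_2": 0.3, "Rx_6": 0.15})
    mol_size_range: tuple[int, int] = (3, 8)
    seed: int = 0
    keep_byproducts: bool = False

    def __post_init__(self) -> None:
        total = sum(self.class_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class weights sum to {total}, expected 1")
        if self.mol_size_range[0] < 2:
            raise ValueError("molecule sizes must be >= 2")
        if self.n_reactions < 1:
            raise ValueError("n_reactions must be >= 1")


def gen_dataset(config: ToyDatasetConfig,
                templates: Optional[dict[str, ToyTemplate]] = None
                ) -> list[ReactionRecord]:
    """Generate ``n_reactions`` valid records with multinomial class mix."""
    templates = templates if templates is not None else TEMPLATES
    for c in config.class_weights:
        if c not in templates:
            raise ValueError(f"no template registered for class {c!r}")
    rng = random.Random(config.seed)
    classes = sorted(config.class_weights)
    weights = [config.class_weights[c] for c in classes]
    records = []
    for _ in range(config.n_reactions):
        rx_class = rng.choices(classes, weights)[0]
        template = templates[rx_class]
        reactants = template.builder(rng, config.mol_size_range)
        records.append(apply_template(template, reactants,
                                      keep_byproducts=config.keep_byproducts))
    return records


# --------------------------------------------------------------------------
# retrieval baseline


def token_edit_distance(a: Sequence[str], b: Sequence[str]) -> int:
    """Plain Levenshtein distance over token sequences (reference DP)."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        ai = a[i - 1]
        for j in range(1, n + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                         prev[j - 1] + (ai != b[j - 1]))
        prev = cur
    return prev[n]


def _encode(strings: Sequence[str]) -> list[np.ndarray]:
    vocab: dict[str, int] = {}
    out = []
    for s in strings:
        toks = char_normalize(s).tokens
        out.append(np.array([vocab.setdefault(t, len(vocab)) for t in toks],
                            dtype=np.int32))
    return out


def _batch_distances(train_ids: list[np.ndarray], query: np.ndarray) -> np.ndarray:
    """Edit distance from ``query`` to every training sequence, vectorized
    across the training set (prefix-min relaxation of the insert term)."""
    n = len(train_ids)
    maxlen = max((len(t) for t in train_ids), default=0)
    T = np.full((n, maxlen), -1, dtype=np.int32)
    L = np.empty(n, dtype=np.int64)
    for i, t in enumerate(train_ids):
        T[i, :len(t)] = t
        L[i] = len(t)
    cols = np.arange(maxlen + 1)
    prev = np.broadcast_to(cols, (n, maxlen + 1)).astype(np.int64).copy()
    for i in range(1, len(query) + 1):
        sub = prev[:, :-1] + (T != query[i - 1])
        dele = prev[:, 1:] + 1
        temp = np.minimum(sub, dele)
        full = np.concatenate([np.full((n, 1), i, dtype=np.int64), temp], axis=1)
        adj = full - cols
        np.minimum.accumulate(adj, axis=1, out=adj)
        prev = adj + cols
    return prev[np.arange(n), L]


def retrieval_predict(train_src: Sequence[str], train_tgt: Sequence[str],
                      query_src: str, beam_width: int) -> BeamSet:
    """Nearest-neighbor predictor: the targets of the ``beam_width`` training
    sources closest to the query by character-token edit distance, ties broken
    by training index.  A deterministic stand-in for a trained seq2seq model."""
    return retrieval_predict_batch(train_src, train_tgt, [query_src],
                                   beam_width)[0]


def retrieval_predict_batch(train_src: Sequence[str], train_tgt: Sequence[str],
                            queries: Sequence[str], beam_width: int
                            ) -> list[BeamSet]:
    if beam_width < 1:
        raise ValueError("beam_width must be >= 1")
    if len(train_src) == 0 or len(train_src) != len(train_tgt):
        raise ValueError("training sources/targets empty or misaligned")
    all_ids = _encode(list(train_src) + list(queries))
    train_ids = all_ids[:len(train_src)]
    query_ids = all_ids[len(train_src):]
    beams = []
    for qi, q in enumerate(query_ids):
        dists = _batch_distances(train_ids, q)
        order = np.argsort(dists, kind="stable")[:beam_width]
        beams.append(BeamSet(source_id=qi,
                             candidates=[train_tgt[i] for i in order],
                             beam_width=beam_width))
    return beams
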