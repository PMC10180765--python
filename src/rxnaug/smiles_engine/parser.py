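"""SMILES parser for the supported subset.

Supported: organic-subset atoms (B, C, N, O, P, S, F, Cl, Br, I and aromatic
b, c, n, o, p, s), bracket atoms with isotope / chirality (@, @@) / H-count /
charge, bond symbols ``- = # : / \\``, branches, ring closures (digits and
``%nn``) and the ``.`` separator.  Anything else is a lexical error.

Parsing never raises for malformed input when using :func:`try_parse` /
:func:`is_valid`; a :class:`ParseDiagnostics` is returned instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from .graph import (
    AROMATIC_ELEMENTS,
    MolGraph,
    Atom,
    SUPPORTED_ELEMENTS,
    compute_implicit_h,
    valence_errors,
)

__all__ = [
    "ParseDiagnostics",
    "SmilesParseError",
    "parse",
    "try_parse",
    "is_valid",
]

ERROR_KINDS = (
    "lex_error",
    "unbalanced_paren",
    "unclosed_ring",
    "bad_bracket_atom",
    "valence_violation",
    "empty",
)


@dataclass
class ParseDiagnostics:
    """Outcome of a parse attempt; ``position`` is a character offset."""

    ok: bool
    error_kind: Optional[str] = None
    position: int = 0
    message: str = ""

    @classmethod
    def success(cls) -> "ParseDiagnostics":
        return cls(ok=True)

    @classmethod
    def failure(cls, kind: str, position: int, message: str) -> "ParseDiagnostics":
        assert kind in ERROR_KINDS
        return cls(ok=False, error_kind=kind, position=position, message=message)


class SmilesParseError(ValueError):
    """Raised by :func:`parse`; carries the diagnostics."""

    def __init__(self, diagnostics: ParseDiagnostics, smiles: str = ""):
        self.diagnostics = diagnostics
        self.smiles = smiles
        super().__init__(
            f"{diagnostics.error_kind} at position {diagnostics.position}: "
            f"{diagnostics.message}" + (f" in {smiles!r}" if smiles else ""))


_BOND_SYMBOLS = {"-": "single", "=": "double", "#": "triple", ":": "aromatic",
                 "/": "single", "\\": "single"}

_BRACKET_RE = re.compile(
    r"""\[
        (?P<isotope>\d+)?
        (?P<symbol>[A-Z][a-z]?|[a-z])
        (?P<chirality>@@?)?
        (?P<hcount>H\d*)?
        (?P<charge>\+{1,2}|-{1,2}|\+\d+|-\d+)?
        \]""",
    re.VERBOSE,
)

_TWO_LETTER = ("Cl", "Br")
_ONE_LETTER = set("BCNOPSFI")
_AROMATIC_LOWER = set("bcnops")


class _Parser:
    def __init__(self, smiles: str, strict_valence: bool):
        self.s = smiles
        self.strict = strict_valence
        self.mol = MolGraph()
        self.pos = 0

    def fail(self, kind: str, message: str, pos: Optional[int] = None):
        return ParseDiagnostics.failure(kind, self.pos if pos is None else pos,
                                        message)

    def run(self):
        s = self.s
        if s == "":
            return None, self.fail("empty", "empty SMILES string")
        prev: Optional[int] = None          # atom awaiting the next bond
        pending: Optional[tuple[str, str, int]] = None  # (order, raw sym, pos)
        stack: list[Optional[int]] = []
        # ring label -> (atom, bond order or None, raw sym or None, open pos)
        rings: dict[str, tuple[int, Optional[str], Optional[str], int]] = {}
        n = len(s)
        while self.pos < n:
            ch = s[self.pos]
            atom = None
            if s.startswith(_TWO_LETTER[0], self.pos) or s.startswith(_TWO_LETTER[1], self.pos):
                atom = Atom(element=s[self.pos:self.pos + 2])
                self.pos += 2
            elif ch in _ONE_LETTER:
                atom = Atom(element=ch)
                self.pos += 1
            elif ch in _AROMATIC_LOWER:
                atom = Atom(element=ch.upper(), aromatic=True)
                self.pos += 1
            elif ch == "[":
                atom, diag = self._bracket_atom()
                if diag is not None:
                    return None, diag
            elif ch in _BOND_SYMBOLS:
                if pending is not None:
                    return None, self.fail("lex_error", "two bond symbols in a row")
                if prev is None:
                    return None, self.fail("lex_error", "bond symbol with no preceding atom")
                pending = (_BOND_SYMBOLS[ch], ch, self.pos)
                self.pos += 1
                continue
            elif ch == "(":
                if prev is None:
                    return None, self.fail("lex_error", "branch opens before any atom")
                if pending is not None:
                    return None, self.fail("lex_error", "bond symbol before '('")
                stack.append(prev)
                self.pos += 1
                continue
            elif ch == ")":
                if not stack:
                    return None, self.fail("unbalanced_paren", "')' without matching '('")
                if pending is not None:
                    return None, self.fail("lex_error", "dangling bond symbol before ')'")
                prev = stack.pop()
                self.pos += 1
                continue
            elif ch.isdigit() or ch == "%":
                diag = self._ring_closure(prev, pending, rings)
                if diag is not None:
                    return None, diag
                pending = None
                continue
            elif ch == ".":
                if stack:
                    return None, self.fail("lex_error", "'.' inside a branch")
                if pending is not None:
                    return None, self.fail("lex_error", "bond symbol before '.'")
                if prev is None:
                    return None, self.fail("lex_error", "'.' with no preceding fragment")
                prev = None
                self.pos += 1
                continue
            else:
                return None, self.fail("lex_error", f"unexpected character {ch!r}")

            # we parsed an atom
            idx = self.mol.add_atom(atom)
            if prev is not None:
                order, raw, _ = pending if pending is not None else (None, None, None)
                if order is None:
                    both_arom = (self.mol.atoms[prev].aromatic and atom.aromatic)
                    order = "aromatic" if both_arom else "single"
                direction = raw if raw in ("/", "\\") else None
                self.mol.add_bond(prev, idx, order,
                                  direction=direction,
                                  dir_from=prev if direction else None)
            elif pending is not None:
                return None, self.fail("lex_error", "bond symbol before first atom of fragment",
                                       pending[2])
            pending = None
            prev = idx

        if stack:
            return None, self.fail("unbalanced_paren", "unclosed '('", n - 1)
        if pending is not None:
            return None, self.fail("lex_error", "trailing bond symbol", pending[2])
        if rings:
            label, (_, _, _, open_pos) = next(iter(rings.items()))
            return None, self.fail("unclosed_ring",
                                   f"ring label {label} never closed", open_pos)

        compute_implicit_h(self.mol)
        if self.strict:
            errs = valence_errors(self.mol)
            if errs:
                return None, self.fail("valence_violation", errs[0][1], 0)
        return self.mol.components(), None

    def _bracket_atom(self):
        m = _BRACKET_RE.match(self.s, self.pos)
        if m is None:
            end = self.s.find("]", self.pos)
            return None, self.fail("bad_bracket_atom",
                                   "malformed bracket atom"
                                   if end >= 0 else "unterminated bracket atom")
        symbol = m.group("symbol")
        aromatic = symbol.islower()
        element = symbol.capitalize() if aromatic else symbol
        if element not in SUPPORTED_ELEMENTS:
            return None, self.fail("bad_bracket_atom",
                                   f"unsupported element {symbol!r}")
        if aromatic and element not in AROMATIC_ELEMENTS:
            return None, self.fail("bad_bracket_atom",
                                   f"element {element} cannot be aromatic")
        hcount = m.group("hcount")
        explicit_h = 0
        if hcount is not None:
            explicit_h = int(hcount[1:]) if len(hcount) > 1 else 1
        charge_s = m.group("charge")
        charge = 0
        if charge_s:
            if charge_s in ("+", "++", "-", "--"):
                charge = charge_s.count("+") - charge_s.count("-")
            else:
                charge = int(charge_s)
        isotope = m.group("isotope")
        atom = Atom(element=element, aromatic=aromatic, formal_charge=charge,
                    explicit_h=explicit_h,
                    isotope=int(isotope) if isotope else None,
                    bracket=True, chirality=m.group("chirality"))
        self.pos = m.end()
        return atom, None

    def _ring_closure(self, prev, pending, rings):
        s = self.s
        if prev is None:
            return self.fail("lex_error", "ring closure with no preceding atom")
        if s[self.pos] == "%":
            if self.pos + 2 >= len(s) or not s[self.pos + 1:self.pos + 3].isdigit():
                return self.fail("lex_error", "'%' must be followed by two digits")
            label = s[self.pos + 1:self.pos + 3]
            self.pos += 3
        else:
            label = s[self.pos]
            self.pos += 1
        order, raw = (pending[0], pending[1]) if pending is not None else (None, None)
        if label not in rings:
            rings[label] = (prev, order, raw, self.pos - 1)
            return None
        partner, p_order, p_raw, _ = rings.pop(label)
        if partner == prev:
            return self.fail("lex_error", f"ring label {label} closes on its own atom")
        if self.mol.bond_between(partner, prev) is not None:
            return self.fail("lex_error",
                             f"ring closure duplicates bond {partner}-{prev}")
        if order is not None and p_order is not None and order != p_order:
            return self.fail("lex_error",
                             f"conflicting bond orders on ring label {label}")
        final = order or p_order
        if final is None:
            both_arom = (self.mol.atoms[partner].aromatic
                         and self.mol.atoms[prev].aromatic)
            final = "aromatic" if both_arom else "single"
        direction = raw if raw in ("/", "\\") else (p_raw if p_raw in ("/", "\\") else None)
        dir_from = prev if raw in ("/", "\\") else (partner if p_raw in ("/", "\\") else None)
        self.mol.add_bond(partner, prev, final, direction=direction, dir_from=dir_from)
        return None


def try_parse(smiles: str, strict_valence: bool = False):
    """Parse without raising.

    Returns ``(components, diagnostics)``; ``components`` is ``None`` on
    failure and ``diagnostics.ok`` reflects the outcome.
    """
    if not isinstance(smiles, str):
        return None, ParseDiagnostics.failure("lex_error", 0, "not a string")
    comps, diag = _Parser(smiles, strict_valence).run()
    if diag is None:
        return comps, ParseDiagnostics.success()
    return None, diag


def parse(smiles: str, strict_valence: bool = False) -> list[MolGraph]:
    """Parse ``smiles`` into connected components or raise :class:`SmilesParseError`."""
    comps, diag = try_parse(smiles, strict_valence)
    if comps is None:
        raise SmilesParseError(diag, smiles)
    return comps


def is_valid(smiles: str, strict_valence: bool = False) -> tuple[bool, ParseDiagnostics]:
    """Grammar (and optionally valence) validity; never raises."""
    comps, diag = try_parse(smiles, strict_valence)
    return comps is not None, diag
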