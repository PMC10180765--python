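"""Tokenization of SMILES for sequence models.

Two schemes are provided: character normalization, which splits a string into
single characters (two-letter element symbols and bracket interiors
included), and atom-level tokenization, which keeps multi-character units —
``Cl``/``Br``, bracket atoms, ``%nn`` ring labels — as single tokens.

Both schemes are lossless: joining the tokens reproduces the input exactly.
Reaction-class conditioning tokens (``RX_<n>``) are a deliberate exception to
character splitting: they stay atomic under both schemes so the label
survives normalization.  A single space is tokenized as a ``' '`` token and
dropped when sequences are serialized to space-separated model files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

__all__ = [
    "TokenSequence",
    "TokenizationError",
    "char_normalize",
    "atom_tokenize",
    "normalize",
    "denormalize",
    "to_line",
    "from_line",
    "write_token_file",
    "read_token_file",
]

SCHEMES = ("character", "atom")


class TokenizationError(ValueError):
    """A character did not match any token class."""


@dataclass
class TokenSequence:
    """Ordered tokens plus the scheme that produced them."""

    tokens: list[str]
    scheme: str

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if any(t == "" for t in self.tokens):
            raise ValueError("empty token")

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)


_CLASS_TOKEN = r"RX_\d+"

_ATOM_TOKEN_RE = re.compile(
    rf"({_CLASS_TOKEN}|\[[^\]]+\]|Br|Cl|%\d{{2}}|[BCNOPSFIHbcnops0-9()=#:/\\.+\-@ ])"
)

_CHAR_TOKEN_RE = re.compile(rf"({_CLASS_TOKEN}|.)")


def char_normalize(smiles: str) -> TokenSequence:
    """Character-based normalization: one token per character.

    ``RX_<n>`` class tokens are kept whole; every other character — including
    the letters of two-letter elements and bracket contents — becomes its own
    token.  Purely lexical, so any string is accepted.
    """
    if smiles == "":
        raise ValueError("empty string")
    tokens = _CHAR_TOKEN_RE.findall(smiles)
    return TokenSequence(tokens=tokens, scheme="character")


def atom_tokenize(smiles: str) -> TokenSequence:
    """Atom-level tokenization: bracket atoms, Cl/Br and %nn stay whole."""
    if smiles == "":
        raise ValueError("empty string")
    tokens = []
    pos = 0
    while pos < len(smiles):
        m = _ATOM_TOKEN_RE.match(smiles, pos)
        if m is None:
            raise TokenizationError(
                f"no token class matches {smiles[pos]!r} at position {pos}")
        tokens.append(m.group(0))
        pos = m.end()
    return TokenSequence(tokens=tokens, scheme="atom")


def normalize(smiles: str, scheme: str) -> TokenSequence:
    if scheme == "character":
        return char_normalize(smiles)
    if scheme == "atom":
        return atom_tokenize(smiles)
    raise ValueError(f"scheme must be one of {SCHEMES}")


def denormalize(seq: TokenSequence) -> str:
    """Exact inverse of both schemes: concatenation of the tokens."""
    if not seq.tokens:
        raise ValueError("empty token sequence")
    return "".join(seq.tokens)


def to_line(seq: TokenSequence) -> str:
    """Space-separated serialization (literal-space tokens are dropped)."""
    return " ".join(t for t in seq.tokens if t != " ")


def from_line(line: str, scheme: str) -> TokenSequence:
    """Rebuild a sequence from a space-separated model-file line.

    Adjacent multi-character tokens that were separated by a literal space in
    the original string (class token vs SMILES) are re-joined with a space
    token on output via :func:`detokenize_line` instead; here tokens are
    taken verbatim.
    """
    tokens = [t for t in line.strip().split(" ") if t]
    return TokenSequence(tokens=tokens, scheme=scheme)


def detokenize_line(line: str) -> str:
    """Collapse a space-separated token line back into a raw string."""
    return "".join(line.split())


def write_token_file(seqs: Iterable[TokenSequence], path) -> None:
    with open(Path(path), "w") as fh:
        for seq in seqs:
            fh.write(to_line(seq) + "\n")


def read_token_file(path, scheme: str) -> list[TokenSequence]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                out.append(from_line(line, scheme))
    return out
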