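"""Scoring of ranked predictions.

A prediction is counted correct only when, after canonicalization, it exactly
matches the reference — i.e. the multiset of canonical '.'-components agrees.
Besides top-k exact-match accuracy the module reports the grammatical-invalid
rate (fraction of decoded candidate strings that fail SMILES parsing) and
per-class breakdowns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .normalization import detokenize_line
from .smiles_engine import canonical, is_valid, try_parse

__all__ = [
    "BeamSet",
    "EvalReport",
    "match_prediction",
    "topk_accuracy",
    "invalid_rate",
    "per_class_report",
    "evaluate",
    "read_nbest",
]

DEFAULT_KS = (1, 3, 5, 10)


@dataclass
class BeamSet:
    """Ranked candidates for one source (rank 1 first)."""

    source_id: int
    candidates: list[str]
    beam_width: int

    def __post_init__(self) -> None:
        if not 1 <= len(self.candidates) <= self.beam_width:
            raise ValueError(
                f"source {self.source_id}: {len(self.candidates)} candidates "
                f"for beam width {self.beam_width}")


@dataclass
class EvalReport:
    """Aggregate metrics; proportions are in [0, 1]."""

    top_k_accuracy: dict[int, float]
    invalid_rate: dict[int, float]
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)
    n_evaluated: int = 0

    def to_dict(self) -> dict:
        return {
            "n_evaluated": self.n_evaluated,
            "top_k_accuracy": {str(k): v for k, v in self.top_k_accuracy.items()},
            "invalid_rate": {str(k): v for k, v in self.invalid_rate.items()},
            "per_class": self.per_class,
        }

    def to_json(self, **kw) -> str:
        kw.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kw)

    def to_table(self) -> str:
        ks = sorted(self.top_k_accuracy)
        lines = [f"n = {self.n_evaluated}",
                 "k     top-k accuracy   invalid rate"]
        for k in ks:
            inv = self.invalid_rate.get(k, float("nan"))
            lines.append(f"{k:<6d}{self.top_k_accuracy[k]:>14.4f}{inv:>15.4f}")
        if self.per_class:
            lines.append("")
            lines.append("class   n      top-1    invalid")
            for c in sorted(self.per_class):
                row = self.per_class[c]
                lines.append(f"{c:<8s}{int(row['n']):<7d}"
                             f"{row['top_1_accuracy']:<9.4f}"
                             f"{row['invalid_rate']:<9.4f}")
        return "\n".join(lines)


class _CanonCache:
    """Memoized canonicalization; invalid strings map to None."""

    def __init__(self) -> None:
        self._cache: dict[str, Optional[str]] = {}

    def get(self, smiles: str) -> Optional[str]:
        if smiles not in self._cache:
            ok, _ = try_parse(smiles)
            self._cache[smiles] = canonical(smiles) if ok else None
        return self._cache[smiles]


def match_prediction(pred: str, ref: str, cache: Optional[_CanonCache] = None) -> bool:
    """True iff ``pred`` parses and its canonical component multiset equals
    the reference's.  An invalid prediction is a mismatch, never an error;
    an invalid reference raises."""
    cache = cache or _CanonCache()
    ref_canon = cache.get(ref)
    if ref_canon is None:
        raise ValueError(f"invalid reference SMILES {ref!r}")
    pred_canon = cache.get(pred)
    return pred_canon is not None and pred_canon == ref_canon


def _first_match_rank(beam: BeamSet, ref: str, cache: _CanonCache) -> Optional[int]:
    for rank, cand in enumerate(beam.candidates, start=1):
        if match_prediction(cand, ref, cache):
            return rank
    return None


def _check_aligned(beams: Sequence[BeamSet], refs: Sequence[str]) -> None:
    if len(beams) == 0:
        raise ValueError("empty evaluation input")
    if len(beams) != len(refs):
        raise ValueError(f"{len(beams)} beam sets vs {len(refs)} references")


def topk_accuracy(beams: Sequence[BeamSet], refs: Sequence[str], k: int,
                  cache: Optional[_CanonCache] = None) -> float:
    """Fraction of sources whose reference matches a candidate of rank <= k."""
    _check_aligned(beams, refs)
    if any(k > b.beam_width for b in beams):
        raise ValueError(f"k={k} exceeds beam width")
    cache = cache or _CanonCache()
    hits = 0
    for beam, ref in zip(beams, refs):
        rank = _first_match_rank(beam, ref, cache)
        if rank is not None and rank <= k:
            hits += 1
    return hits / len(beams)


def invalid_rate(beams: Sequence[BeamSet], k: int, strict_valence: bool = False,
                 per_source: bool = False) -> float:
    """Grammatically invalid fraction among candidates at ranks 1..k.

    Pooled over all candidates by default (the primary definition); with
    ``per_source`` it is instead the fraction of sources having at least one
    invalid candidate within the top k.
    """
    if len(beams) == 0:
        raise ValueError("empty evaluation input")
    n_bad = 0
    n_tot = 0
    n_src_bad = 0
    for beam in beams:
        bad = sum(1 for cand in beam.candidates[:k]
                  if not is_valid(cand, strict_valence)[0])
        n_bad += bad
        n_tot += len(beam.candidates[:k])
        n_src_bad += bool(bad)
    if per_source:
        return n_src_bad / len(beams)
    return n_bad / n_tot


def per_class_report(beams: Sequence[BeamSet], refs: Sequence[str],
                     classes: Sequence[str],
                     cache: Optional[_CanonCache] = None) -> dict[str, dict[str, float]]:
    """Top-1 accuracy and top-1 invalid rate within each reaction class."""
    _check_aligned(beams, refs)
    if len(classes) != len(beams):
        raise ValueError("class labels misaligned with beams")
    cache = cache or _CanonCache()
    groups: dict[str, list[int]] = {}
    for i, c in enumerate(classes):
        groups.setdefault(c, []).append(i)
    out = {}
    for c, idxs in groups.items():
        sub_beams = [beams[i] for i in idxs]
        sub_refs = [refs[i] for i in idxs]
        out[c] = {
            "n": float(len(idxs)),
            "top_1_accuracy": topk_accuracy(sub_beams, sub_refs, 1, cache),
            "invalid_rate": invalid_rate(sub_beams, 1),
        }
    return out


def evaluate(beams: Sequence[BeamSet], refs: Sequence[str],
             classes: Optional[Sequence[str]] = None,
             ks: Iterable[int] = DEFAULT_KS,
             strict_valence: bool = False) -> EvalReport:
    """Full report: top-k accuracies, invalid rates, optional per-class table."""
    _check_aligned(beams, refs)
    cache = _CanonCache()
    max_k = max(b.beam_width for b in beams)
    ks = [k for k in ks if k <= max_k]
    report = EvalReport(
        top_k_accuracy={k: topk_accuracy(beams, refs, k, cache) for k in ks},
        invalid_rate={k: invalid_rate(beams, k, strict_valence) for k in ks},
        n_evaluated=len(beams),
    )
    if classes is not None:
        report.per_class = per_class_report(beams, refs, classes, cache)
    return report


def read_nbest(path, beam_width: int, detokenize: bool = True) -> list[BeamSet]:
    """Read an n-best prediction file: ``beam_width`` consecutive lines per
    source, rank-major.  Token lines (space-separated) are collapsed back to
    raw strings unless ``detokenize`` is off."""
    if beam_width < 1:
        raise ValueError("beam_width must be >= 1")
    lines = Path(path).read_text().splitlines()
    if len(lines) % beam_width != 0:
        raise ValueError(
            f"{len(lines)} lines is not a multiple of beam width {beam_width}")
    beams = []
    for i in range(0, len(lines), beam_width):
        cands = [detokenize_line(l) if detokenize else l.strip()
                 for l in lines[i:i + beam_width]]
        beams.append(BeamSet(source_id=i // beam_width,
                             candidates=cands, beam_width=beam_width))
    return beams
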