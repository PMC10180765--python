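"""Reaction dataset I/O, class-token conditioning and train/test splitting.

The on-disk format is line-oriented reaction SMILES
(``reactants>reagents>products``, one reaction per line), optionally followed
by a tab and a reaction-class label ``Rx_1`` .. ``Rx_10``.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

from .smiles_engine import try_parse

__all__ = [
    "RX_CLASSES",
    "ReactionRecord",
    "TaskSpec",
    "RsmiFormatError",
    "read_rsmi",
    "write_rsmi",
    "make_src_tgt",
    "split_train_test",
]

RX_CLASSES = tuple(f"Rx_{i}" for i in range(1, 11))

TASKS = ("forward", "retro", "retro_with_class")


class RsmiFormatError(ValueError):
    """Malformed reaction line; carries the 1-based line number."""

    def __init__(self, line_no: int, message: str):
        self.line_no = line_no
        super().__init__(f"line {line_no}: {message}")


@dataclass
class ReactionRecord:
    """One reaction: reactants/reagents/products plus optional class label
    and train/test partition tag."""

    reactants: list[str]
    reagents: list[str] = field(default_factory=list)
    products: list[str] = field(default_factory=list)
    rx_class: Optional[str] = None
    partition_tag: Optional[str] = None

    def validate(self) -> None:
        if not self.reactants:
            raise ValueError("empty reactant side")
        if not self.products:
            raise ValueError("empty product side")
        for side, strings in (("reactant", self.reactants),
                              ("reagent", self.reagents),
                              ("product", self.products)):
            for s in strings:
                ok, diag = try_parse(s)
                if not ok:
                    raise ValueError(
                        f"invalid {side} SMILES {s!r}: {diag.error_kind} "
                        f"({diag.message})")
        if self.rx_class is not None and self.rx_class not in RX_CLASSES:
            raise ValueError(f"unknown reaction class {self.rx_class!r}")
        if self.partition_tag not in (None, "train", "test"):
            raise ValueError(f"bad partition tag {self.partition_tag!r}")

    def to_line(self, with_class: bool = False) -> str:
        rsmi = ">".join(".".join(side) for side in
                        (self.reactants, self.reagents, self.products))
        if with_class:
            if self.rx_class is None:
                raise ValueError("record has no class label")
            return f"{rsmi}\t{self.rx_class}"
        return rsmi

    def tagged(self, tag: str) -> "ReactionRecord":
        return replace(self, partition_tag=tag)


@dataclass
class TaskSpec:
    """Which prediction task source/target pairs are prepared for.

    ``class_token_format`` renders the conditioning token from the 1-based
    class number (default ``RX_%d``); ``include_reagents`` adds the middle
    '>' field to the forward-task source.
    """

    task: str = "retro"
    class_token_format: str = "RX_%d"
    include_reagents: bool = False

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")

    def class_token(self, rx_class: str) -> str:
        m = re.fullmatch(r"Rx_(\d+)", rx_class)
        if m is None:
            raise ValueError(f"unknown reaction class {rx_class!r}")
        return self.class_token_format % int(m.group(1))


def _parse_line(line: str, line_no: int, with_class: bool) -> ReactionRecord:
    if with_class:
        parts = line.split("\t")
        if len(parts) != 2:
            raise RsmiFormatError(line_no, "expected 'rsmi<TAB>class'")
        rsmi, rx_class = parts[0].strip(), parts[1].strip()
    else:
        rsmi, rx_class = line.strip(), None
        if "\t" in rsmi:
            rsmi = rsmi.split("\t", 1)[0]
    fields = rsmi.split(">")
    if len(fields) != 3:
        raise RsmiFormatError(
            line_no, f"expected exactly 2 '>' separators, found {rsmi.count('>')}")
    reactants = [s for s in fields[0].split(".") if s] if fields[0] else []
    reagents = [s for s in fields[1].split(".") if s] if fields[1] else []
    products = [s for s in fields[2].split(".") if s] if fields[2] else []
    rec = ReactionRecord(reactants=reactants, reagents=reagents,
                         products=products, rx_class=rx_class)
    try:
        rec.validate()
    except ValueError as exc:
        raise RsmiFormatError(line_no, str(exc)) from exc
    return rec


def read_rsmi(path, with_class: bool = False) -> list[ReactionRecord]:
    """Read a reaction-SMILES file; every line must yield a valid record."""
    records = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            records.append(_parse_line(line, line_no, with_class))
    return records


def write_rsmi(records: Iterable[ReactionRecord], path, with_class: bool = False) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_line(with_class) + "\n")


def make_src_tgt(records: list[ReactionRecord],
                 spec: TaskSpec) -> tuple[list[str], list[str]]:
    """Line-aligned source/target string lists for a task.

    forward:            src = reactants (+ reagents per flag), tgt = products
    retro:              src = products, tgt = reactants
    retro_with_class:   retro with the class token prepended to src
                        (space-separated; kept atomic by the tokenizers)
    """
    src, tgt = [], []
    for i, rec in enumerate(records):
        reactant_side = list(rec.reactants)
        if spec.task == "forward" and spec.include_reagents:
            reactant_side += rec.reagents
        r = ".".join(reactant_side)
        p = ".".join(rec.products)
        if spec.task == "forward":
            src.append(r)
            tgt.append(p)
        elif spec.task == "retro":
            src.append(p)
            tgt.append(r)
        else:
            if rec.rx_class is None:
                raise ValueError(f"record {i}: retro_with_class requires a "
                                 "class label on every record")
            src.append(f"{spec.class_token(rec.rx_class)} {p}")
            tgt.append(r)
    return src, tgt


def split_train_test(records: list[ReactionRecord], test_fraction: float,
                     seed: int, stratify: bool = False
                     ) -> tuple[list[ReactionRecord], list[ReactionRecord]]:
    """Deterministic disjoint train/test split; partition tags are set.

    The test size is ``round(n * test_fraction)``.  With ``stratify`` the
    per-class test counts follow largest-remainder apportionment, keeping
    class proportions within one record of exact.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    n_test = int(round(n * test_fraction))
    rng = random.Random(seed)

    if not stratify:
        idx = list(range(n))
        rng.shuffle(idx)
        test_idx = set(idx[:n_test])
    else:
        by_class: dict[Optional[str], list[int]] = {}
        for i, rec in enumerate(records):
            by_class.setdefault(rec.rx_class, []).append(i)
        quotas = {c: len(members) * test_fraction for c, members in by_class.items()}
        base = {c: int(q) for c, q in quotas.items()}
        short = n_test - sum(base.values())
        remainders = sorted(quotas, key=lambda c: (quotas[c] - base[c], str(c)),
                            reverse=True)
        for c in remainders[:max(short, 0)]:
            base[c] += 1
        test_idx = set()
        for c in sorted(by_class, key=str):
            members = list(by_class[c])
            rng.shuffle(members)
            test_idx.update(members[:base[c]])

    train = [rec.tagged("train") for i, rec in enumerate(records) if i not in test_idx]
    test = [rec.tagged("test") for i, rec in enumerate(records) if i in test_idx]
    return train, test
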