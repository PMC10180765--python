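"""N-level dataset augmentation by SMILES enumeration.

Each training reaction is replaced by N variants; every compound on the
source side is independently rewritten with a randomly enumerated SMILES,
so level 1 reduces to the original (canonicalized) dataset.  Augmentation is
a training-time operation only: records tagged as test are rejected.
"""

from __future__ import annotations

import hashlib
import random
from dataclasses import dataclass

from .reaction_io import ReactionRecord
from .smiles_engine import canonical, parse, random_smiles

__all__ = ["AugmentationConfig", "augment_compound", "augment_dataset"]


@dataclass
class AugmentationConfig:
    """Settings for N-level augmentation.

    ``level_n`` is the number of variants per record; ``keep_original_first``
    makes the first variant the canonical original; ``source_side`` names the
    model-input side of the record ('reactants' for forward prediction,
    'products' for retrosynthesis) — that side is enumerated while the other
    (target) side stays canonical unless ``augment_target_side``;
    ``shuffle_components`` additionally shuffles '.'-components within a
    multi-component compound string.  Reagents follow the reactants' side.
    """

    level_n: int = 1
    seed: int = 0
    source_side: str = "reactants"
    augment_target_side: bool = False
    keep_original_first: bool = True
    shuffle_components: bool = False

    def __post_init__(self) -> None:
        if self.level_n < 1:
            raise ValueError("level_n must be >= 1")
        if self.source_side not in ("reactants", "products"):
            raise ValueError("source_side must be 'reactants' or 'products'")


def _draw_rng(seed: int, record_index: int, draw: int, compound: int) -> random.Random:
    """Deterministic per-(record, draw, compound) RNG, independent of order of use."""
    key = f"{seed}:{record_index}:{draw}:{compound}".encode()
    return random.Random(int.from_bytes(hashlib.sha256(key).digest()[:8], "big"))


def _enumerated(smiles: str, rng: random.Random, shuffle_components: bool) -> str:
    comps = parse(smiles)
    parts = [random_smiles(c, rng) for c in comps]
    if shuffle_components and len(parts) > 1:
        rng.shuffle(parts)
    return ".".join(parts)


def augment_compound(smiles: str, config: AugmentationConfig,
                     record_index: int = 0, compound_index: int = 0) -> list[str]:
    """N equivalent SMILES for one compound string (with replacement).

    The first entry is ``canonical(smiles)`` when ``keep_original_first``;
    every entry canonicalizes back to ``canonical(smiles)``.
    """
    out = []
    draws = range(config.level_n)
    if config.keep_original_first:
        out.append(canonical(smiles))
        draws = range(1, config.level_n)
    for j in draws:
        rng = _draw_rng(config.seed, record_index, j, compound_index)
        out.append(_enumerated(smiles, rng, config.shuffle_components))
    return out


def augment_dataset(train: list[ReactionRecord],
                    config: AugmentationConfig) -> list[ReactionRecord]:
    """Expand ``train`` to ``level_n x len(train)`` records.

    Record ``i``'s j-th variant rewrites each source-side compound with an
    independent random SMILES; the target side is canonicalized (or also
    enumerated when ``augment_target_side``).  Class labels and the train
    partition tag are copied.  Raises if any record is tagged test, or on the
    first invalid record (error message carries its index).
    """
    for i, rec in enumerate(train):
        if rec.partition_tag == "test":
            raise ValueError(
                f"record {i} is tagged 'test'; augmentation applies to the "
                "training partition only")

    out: list[ReactionRecord] = []
    for i, rec in enumerate(train):
        try:
            variants = _augment_record(rec, config, i)
        except Exception as exc:
            raise ValueError(f"record {i}: {exc}") from exc
        out.extend(variants)
    return out


def _augment_record(rec: ReactionRecord, config: AugmentationConfig,
                    record_index: int) -> list[ReactionRecord]:
    variants = []
    for j in range(config.level_n):
        original = config.keep_original_first and j == 0

        def render(compound: str, compound_index: int, augment: bool) -> str:
            if original or not augment:
                return canonical(compound)
            rng = _draw_rng(config.seed, record_index, j, compound_index)
            return _enumerated(compound, rng, config.shuffle_components)

        reactants_are_source = config.source_side == "reactants"
        aug_reactants = reactants_are_source or config.augment_target_side
        aug_products = (not reactants_are_source) or config.augment_target_side
        # compound_index offsets keep reactant/reagent/product draws independent
        reactants = [render(s, k, aug_reactants) for k, s in enumerate(rec.reactants)]
        base = len(rec.reactants)
        reagents = [render(s, base + k, aug_reactants)
                    for k, s in enumerate(rec.reagents)]
        base += len(rec.reagents)
        products = [render(s, base + k, aug_products)
                    for k, s in enumerate(rec.products)]
        variants.append(ReactionRecord(
            reactants=reactants, reagents=reagents, products=products,
            rx_class=rec.rx_class, partition_tag=rec.partition_tag))
    return variants
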