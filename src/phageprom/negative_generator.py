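"""Hard-negative construction by partial block shuffling.

Non-promoter training examples are derived from the promoters themselves
rather than sampled from non-coding DNA, which would make the two classes
trivially separable. Each positive sequence is cut into ``n_blocks``
contiguous blocks (default 8); ``n_shuffled`` of them (default 5) are chosen
at random and rearranged among their slots by a random derangement (every
chosen block moves), while the remaining blocks stay in place. With the
defaults this conserves 3 of 8 blocks — about 35-40% of nucleotide positions
at their original location — so a negative shares substantial local sequence
with its source promoter and the classifier has to learn more than gross
composition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .sequence_io import DataError, SequenceDataset, SequenceRecord

logger = logging.getLogger("phageprom")


@dataclass(frozen=True)
class ShuffleConfig:
    """Parameters of the block-shuffling negative generator."""

    n_blocks: int = 8
    n_shuffled: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_shuffled < self.n_blocks:
            raise DataError(
                f"need 0 < n_shuffled < n_blocks, got "
                f"{self.n_shuffled} / {self.n_blocks}"
            )


def split_blocks(seq: str, n_blocks: int) -> list[str]:
    """Split ``seq`` into ``n_blocks`` contiguous blocks of near-equal size.

    Block sizes differ by at most one; the remainder is front-loaded, so for a
    99-mer and 8 blocks the sizes are [13, 13, 13, 12, 12, 12, 12, 12]. The
    blocks concatenate back to ``seq``.
    """
    L = len(seq)
    if n_blocks > L:
        raise DataError(f"cannot split a {L}-mer into {n_blocks} blocks")
    base, extra = divmod(L, n_blocks)
    blocks = []
    pos = 0
    for i in range(n_blocks):
        size = base + (1 if i < extra else 0)
        blocks.append(seq[pos : pos + size])
        pos += size
    return blocks


def _derangement(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform random permutation of range(n) with no fixed point."""
    if n < 2:
        raise DataError("derangement requires at least 2 elements")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def generate_negative(
    seq: str, cfg: ShuffleConfig, rng: np.random.Generator | None = None
) -> str:
    """Produce one hard negative from a positive sequence.

    ``n_shuffled`` block slots are selected uniformly at random; the blocks in
    those slots are rearranged by a uniform random derangement (none stays in
    its own slot) and re-cut to the slot sizes, while the unselected blocks
    keep their exact positions. Output length and base composition are always
    conserved; when all blocks are equally sized (length divisible by
    ``n_blocks``) the block multiset is conserved too and the operation is a
    pure block permutation. Deterministic given ``cfg.seed`` when no generator
    is passed.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    blocks = split_blocks(seq, cfg.n_blocks)
    selected = np.sort(rng.choice(cfg.n_blocks, size=cfg.n_shuffled, replace=False))
    perm = _derangement(rng, cfg.n_shuffled)
    # re-cut the deranged content to the selected slots' sizes so unselected
    # blocks stay at their original coordinates even when sizes differ by 1
    content = "".join(blocks[selected[perm[j]]] for j in range(cfg.n_shuffled))
    out = list(blocks)
    pos = 0
    for slot in selected:
        size = len(blocks[slot])
        out[slot] = content[pos : pos + size]
        pos += size
    return "".join(out)


def build_negative_set(ds: SequenceDataset, cfg: ShuffleConfig) -> SequenceDataset:
    """One negative per positive; ids suffixed ``_neg``, labels ``non_promoter``.

    Each record uses an independent RNG substream derived from
    ``(cfg.seed, record index)`` so results do not depend on dataset slicing
    order.
    """
    if len(ds) == 0:
        logger.warning("build_negative_set called on an empty dataset")
        return SequenceDataset([])
    negatives = []
    for i, rec in enumerate(ds):
        rng = np.random.default_rng([cfg.seed, i])
        neg = generate_negative(rec.seq, cfg, rng=rng)
        negatives.append(
            SequenceRecord(id=f"{rec.id}_neg", seq=neg, label="non_promoter")
        )
    return SequenceDataset(negatives)


def conserved_fraction(original: str, negative: str, cfg: ShuffleConfig) -> float:
    """Fraction of positions lying in blocks identical to the original slot.

    Both sequences are cut with the same block grid; a position counts as
    conserved when its whole block matches the original block at that slot
    (this also credits shuffled blocks that coincide in content by chance).
    """
    if len(original) != len(negative):
        raise DataError(
            f"length mismatch: {len(original)} vs {len(negative)}"
        )
    orig_blocks = split_blocks(original, cfg.n_blocks)
    neg_blocks = split_blocks(negative, cfg.n_blocks)
    conserved = sum(
        len(ob) for ob, nb in zip(orig_blocks, neg_blocks) if ob == nb
    )
    return conserved / len(original)
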