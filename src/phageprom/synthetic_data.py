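"""Synthetic promoter benchmark generator.

Produces labeled 99-bp sequence sets with the structure the classifier
assumes, so every stage of the pipeline is testable without downloads:

* *host-style* promoters carry degenerate sigma70-like -35 (TTGACA) and -10
  (TATAAT) boxes at loosely constrained positions;
* *phage-style* promoters carry a longer, better-conserved single-RNAP
  recognition element (a T7-like consensus) at a loose position — this is the
  motif substitution distinguishing the two promoter subclasses;
* layer-1 negatives are hard negatives built by the block-shuffling generator
  from the positives themselves, so they share 35-40% conserved blocks with
  their source promoters by construction.

The motif model is consensus + i.i.d. per-base mutation (no PWM sampling),
keeping test expectations transparent. Background composition is uniform
A/C/G/T by default; real phage promoter regions tend to be AT-rich, so an
optional AT-richness knob exists but is off by default. This is a fixture
generator, not a biological promoter simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .negative_generator import ShuffleConfig, build_negative_set
from .sequence_io import DataError, SequenceDataset, SequenceRecord

BASES = "ACGT"


@dataclass(frozen=True)
class MotifSpec:
    """A degenerate motif: consensus, start-position window, mutation rate."""

    consensus: str
    window: tuple[int, int]  # inclusive start-position range (0-based)
    mutation_rate: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_rate <= 0.5:
            raise DataError(
                f"mutation_rate must be in [0, 0.5], got {self.mutation_rate}"
            )
        if self.window[0] > self.window[1] or self.window[0] < 0:
            raise DataError(f"bad motif window {self.window}")


@dataclass(frozen=True)
class SyntheticRecipe:
    """Study conditions for the synthetic benchmark.

    Defaults: 500 sequences per class, 99 bp, uniform background. Host
    promoters carry an AT-tract UP element plus degenerate -35/-10 boxes (5%
    per-base mutation each, start positions jittered by +/-2 bp); phage
    promoters carry a conserved 23-bp T7 phi10-class consensus (2% per-base
    mutation, +/-2 bp jitter).
    """

    n_per_class: int = 500
    length: int = 99
    promoter_motifs: tuple[MotifSpec, ...] = (
        MotifSpec("AAAATTTT", (3, 7), 0.05),
        MotifSpec("TTGACA", (20, 24), 0.05),
        MotifSpec("TATAAT", (48, 52), 0.05),
    )
    phage_motif: MotifSpec = MotifSpec("TAATACGACTCACTATAGGGAGA", (37, 41), 0.02)
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    shuffle: ShuffleConfig = field(default_factory=ShuffleConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        for m in (*self.promoter_motifs, self.phage_motif):
            if m.window[1] + len(m.consensus) > self.length:
                raise DataError(
                    f"motif {m.consensus} window {m.window} exceeds length "
                    f"{self.length}"
                )
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise DataError("background frequencies must sum to 1")


def _implant(seq: list[str], motif: MotifSpec, rng: np.random.Generator) -> None:
    start = int(rng.integers(motif.window[0], motif.window[1] + 1))
    for i, base in enumerate(motif.consensus):
        if rng.random() < motif.mutation_rate:
            base = BASES[rng.integers(0, 4)]
        seq[start + i] = base


def _sample_promoter(
    r: SyntheticRecipe, subclass: str, rng: np.random.Generator
) -> str:
    seq = list(
        rng.choice(list(BASES), size=r.length, p=np.asarray(r.background))
    )
    motifs = (r.phage_motif,) if subclass == "phage" else r.promoter_motifs
    for m in motifs:
        _implant(seq, m, rng)
    return "".join(seq)


def generate_layer1_set(r: SyntheticRecipe) -> SequenceDataset:
    """Layer-1 benchmark: n promoters plus n block-shuffled hard negatives.

    Positives are an even mix of host-style and phage-style promoters (so the
    promoter gate learns features shared by both subclasses); negatives come
    from :func:`build_negative_set` applied to the positives. Deterministic
    given ``r.seed``.
    """
    rng = np.random.default_rng([r.seed, 1])
    positives = []
    for i in range(r.n_per_class):
        subclass = "phage" if i % 2 == 0 else "host"
        positives.append(
            SequenceRecord(
                id=f"prom_{i:05d}",
                seq=_sample_promoter(r, subclass, rng),
                label="promoter",
            )
        )
    pos_ds = SequenceDataset(positives)
    neg_ds = build_negative_set(
        pos_ds, ShuffleConfig(r.shuffle.n_blocks, r.shuffle.n_shuffled, r.seed)
    )
    return SequenceDataset(list(pos_ds) + list(neg_ds))


def generate_layer2_set(
    r: SyntheticRecipe, n_phage: int | None = None, n_host: int | None = None
) -> SequenceDataset:
    """Layer-2 benchmark: phage vs host promoters, optionally unbalanced.

    Pass e.g. ``n_phage=111, n_host=382`` to mimic a realistically imbalanced
    training set; defaults to ``r.n_per_class`` for both classes.
    """
    n_phage = r.n_per_class if n_phage is None else n_phage
    n_host = r.n_per_class if n_host is None else n_host
    rng = np.random.default_rng([r.seed, 2])
    records = []
    for i in range(n_phage):
        records.append(
            SequenceRecord(
                id=f"phage_{i:05d}",
                seq=_sample_promoter(r, "phage", rng),
                label="phage",
            )
        )
    for i in range(n_host):
        records.append(
            SequenceRecord(
                id=f"host_{i:05d}",
                seq=_sample_promoter(r, "host", rng),
                label="host",
            )
        )
    return SequenceDataset(records)


def generate_threeway_set(r: SyntheticRecipe, n_each: int) -> SequenceDataset:
    """Held-out evaluation set with n_each phage, host and non-promoter records.

    Non-promoters are hard negatives shuffled from fresh promoters. Labels use
    the dataset vocabulary (phage / host / non_promoter).
    """
    rng = np.random.default_rng([r.seed, 3])
    records = []
    for i in range(n_each):
        records.append(
            SequenceRecord(
                id=f"ev_phage_{i:05d}",
                seq=_sample_promoter(r, "phage", rng),
                label="phage",
            )
        )
        records.append(
            SequenceRecord(
                id=f"ev_host_{i:05d}",
                seq=_sample_promoter(r, "host", rng),
                label="host",
            )
        )
    source = SequenceDataset(
        [
            SequenceRecord(
                id=f"ev_src_{i:05d}",
                seq=_sample_promoter(r, "phage" if i % 2 == 0 else "host", rng),
                label="promoter",
            )
            for i in range(n_each)
        ]
    )
    negs = build_negative_set(
        source, ShuffleConfig(r.shuffle.n_blocks, r.shuffle.n_shuffled, r.seed + 9)
    )
    for rec in negs:
        records.append(rec)
    return SequenceDataset(records)
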