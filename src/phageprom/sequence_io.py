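"""Reading, validating and writing DNA sequence datasets.

The classifier operates on promoter-length fragments: every model input is at
most 99 bp (shorter sequences are zero-padded at encoding time, never here).
Sequences are uppercase over the alphabet {A, C, G, T, N}; ``N`` is accepted on
input and handled downstream (zero rows in positional encodings, excluded from
composition counts).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("phageprom")

MODEL_INPUT_LENGTH = 99
VALID_ALPHABET = frozenset("ACGTN")

#: class labels used across the two layers
LABELS = ("promoter", "non_promoter", "phage", "host")


class PhagePromError(Exception):
    """Base class for package errors."""


class FastaParseError(PhagePromError):
    """Malformed FASTA input."""


class DataError(PhagePromError):
    """Invalid sequence data or labels."""


@dataclass(frozen=True)
class SequenceRecord:
    """One identified DNA sequence with an optional class label."""

    id: str
    seq: str
    label: str | None = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in LABELS:
            raise DataError(
                f"record {self.id!r}: unknown label {self.label!r}; "
                f"expected one of {LABELS}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class SequenceDataset:
    """Ordered collection of :class:`SequenceRecord` with unique ids."""

    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        dupes = [i for i, c in Counter(ids).items() if c > 1]
        if dupes:
            raise DataError(f"duplicate sequence ids: {sorted(dupes)[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SequenceDataset):
            return NotImplemented
        return self.records == other.records

    @property
    def class_counts(self) -> dict[str, int]:
        return dict(Counter(r.label for r in self.records if r.label is not None))

    def subset(self, indices: Sequence[int]) -> "SequenceDataset":
        return SequenceDataset([self.records[i] for i in indices])

    def with_labels(self, labels: dict[str, str]) -> "SequenceDataset":
        """Attach labels by record id; every id must be covered."""
        missing = [r.id for r in self.records if r.id not in labels]
        if missing:
            raise DataError(f"label file missing ids: {missing[:5]}")
        return SequenceDataset(
            [replace(r, label=labels[r.id]) for r in self.records]
        )

    def sequences(self) -> list[str]:
        return [r.seq for r in self.records]

    def labels(self) -> list[str | None]:
        return [r.label for r in self.records]


def read_fasta(path: str | Path) -> SequenceDataset:
    """Parse a (multi-record) FASTA file into a :class:`SequenceDataset`.

    Sequences are uppercased; record order is preserved. Raises
    :class:`FastaParseError` on malformed input naming the offending line,
    and on empty files.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected '>' header, got {line.strip()[:30]!r}"
                )
            break
        else:
            raise FastaParseError(f"{path}: empty FASTA file")
    records = [
        SequenceRecord(id=rec.id, seq=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return SequenceDataset(records)


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column ``id<TAB>label`` TSV into a dict."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataError(f"{path}: line {lineno}: expected 'id<TAB>label'")
            labels[parts[0]] = parts[1]
    return labels


def validate_sequence(
    rec: SequenceRecord, max_len: int = MODEL_INPUT_LENGTH
) -> SequenceRecord:
    """Check length and alphabet; return the (uppercased) record.

    Raises :class:`DataError` for sequences longer than ``max_len`` (the model
    takes fixed 99-bp inputs; longer sequences are rejected, not truncated) or
    containing characters outside {A, C, G, T, N}.
    """
    seq = rec.seq.upper()
    if len(seq) == 0:
        raise DataError(f"record {rec.id!r}: empty sequence")
    if len(seq) > max_len:
        raise DataError(
            f"record {rec.id!r}: length {len(seq)} exceeds maximum {max_len}"
        )
    bad = set(seq) - VALID_ALPHABET
    if bad:
        raise DataError(
            f"record {rec.id!r}: illegal characters {sorted(bad)}; "
            "sequences must contain only A, C, G, T (N tolerated)"
        )
    n_frac = seq.count("N") / len(seq)
    if n_frac > 0:
        logger.debug("record %s: %.1f%% ambiguous bases", rec.id, 100 * n_frac)
    return replace(rec, seq=seq)


def validate_dataset(
    ds: SequenceDataset, max_len: int = MODEL_INPUT_LENGTH
) -> SequenceDataset:
    return SequenceDataset([validate_sequence(r, max_len) for r in ds])


def write_fasta(ds: SequenceDataset, path: str | Path) -> None:
    """Write a dataset to FASTA (one unwrapped sequence line per record)."""
    path = Path(path)
    if len(ds) == 0:
        logger.warning("writing empty FASTA file to %s", path)
    with open(path, "w") as fh:
        for rec in ds:
            fh.write(f">{rec.id}\n{rec.seq}\n")


def write_labels(ds: SequenceDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in ds:
            if rec.label is not None:
                fh.write(f"{rec.id}\t{rec.label}\n")


def split_train_test(
    ds: SequenceDataset, test_fraction: float, seed: int
) -> tuple[SequenceDataset, SequenceDataset]:
    """Stratified train/test split (e.g. the 80/20 protocol of layer 2).

    The partition is exact (no overlap, union equals the input) and
    deterministic given ``seed``; class ratios are preserved within one record
    per class.
    """
    if not 0 < test_fraction < 1:
        raise DataError(f"test_fraction must be in (0, 1), got {test_fraction}")
    by_label: dict[str | None, list[int]] = {}
    for i, rec in enumerate(ds):
        by_label.setdefault(rec.label, []).append(i)
    for label, idx in by_label.items():
        if len(idx) < 2:
            raise DataError(
                f"class {label!r} has {len(idx)} member(s); need >= 2 to stratify"
            )
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    train_idx: list[int] = []
    for label in sorted(by_label, key=str):
        idx = np.array(by_label[label])
        n_test = int(round(test_fraction * len(idx)))
        n_test = min(max(n_test, 1), len(idx) - 1)
        perm = rng.permutation(len(idx))
        test_idx.extend(idx[perm[:n_test]].tolist())
        train_idx.extend(idx[perm[n_test:]].tolist())
    return ds.subset(sorted(train_idx)), ds.subset(sorted(test_idx))
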