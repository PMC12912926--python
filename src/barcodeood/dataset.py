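"""Core containers: sequence records and genus-level datasets.

A :class:`GenusDataset` is a labeled collection of aligned barcode sequences
from one genus, the unit on which every preparation, distance and
classification step operates.  All sequences in a dataset share one
alignment length; species labels and an ID/OOD partition tag are carried per
record.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from enum import Enum
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "Partition",
    "SequenceRecord",
    "GenusDataset",
    "SplitDataset",
    "BASE_CODES",
    "encode_codes",
]


class Partition(str, Enum):
    """Reference-membership tag: ID species are in the reference, OOD are not."""

    ID = "ID"
    OOD = "OOD"
    UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class SequenceRecord:
    """One specimen: identifier, species label, aligned sequence, partition."""

    sample_id: str
    species: str
    sequence: str
    partition: Partition = Partition.UNASSIGNED

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.sample_id!r} has an empty sequence")

    def with_sequence(self, sequence: str) -> "SequenceRecord":
        return replace(self, sequence=sequence)

    def with_partition(self, partition: Partition) -> "SequenceRecord":
        return replace(self, partition=partition)

    @property
    def ungapped_length(self) -> int:
        return sum(1 for c in self.sequence if c not in "-.")


# Numeric codes used by the distance machinery. Purines are {A=0, G=2} and
# pyrimidines {C=1, T=3}, so ``code ^ 2`` is the transition partner and
# ``code ^ 1`` / ``code ^ 3`` the two transversion partners. Anything that is
# not a canonical base (ambiguity codes, gaps) maps to 255.
BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _b, _c in BASE_CODES.items():
    _CODE_TABLE[ord(_b)] = _c
    _CODE_TABLE[ord(_b.lower())] = _c
CODE_TO_BASE = np.array(list("ACGT"))


def encode_codes(sequences: Iterable[str]) -> np.ndarray:
    """Encode sequences as an (n, L) uint8 matrix (A=0, C=1, G=2, T=3, other=255)."""
    seqs = list(sequences)
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    buf = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return _CODE_TABLE[buf].reshape(len(seqs), len(seqs[0]))


class GenusDataset:
    """An ordered collection of :class:`SequenceRecord` sharing one alignment length."""

    def __init__(
        self,
        records: Sequence[SequenceRecord],
        metadata: Mapping[str, object] | None = None,
        validate: bool = True,
    ) -> None:
        self.records: list[SequenceRecord] = list(records)
        self.metadata: dict[str, object] = dict(metadata or {})
        if validate and self.records:
            length = len(self.records[0].sequence)
            for rec in self.records:
                if len(rec.sequence) != length:
                    raise ValueError(
                        "alignment length mismatch: record "
                        f"{rec.sample_id!r} has length {len(rec.sequence)}, "
                        f"expected {length}"
                    )
            ids = [r.sample_id for r in self.records]
            if len(set(ids)) != len(ids):
                raise ValueError("duplicate sample ids in dataset")

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenusDataset):
            return NotImplemented
        return self.records == other.records

    # -- views -------------------------------------------------------------
    @property
    def alignment_length(self) -> int:
        if not self.records:
            raise ValueError("empty dataset has no alignment length")
        return len(self.records[0].sequence)

    @property
    def species(self) -> list[str]:
        return sorted({r.species for r in self.records})

    def species_counts(self) -> dict[str, int]:
        return dict(Counter(r.species for r in self.records))

    def records_of(self, species: str) -> list[SequenceRecord]:
        return [r for r in self.records if r.species == species]

    def partition_records(self, partition: Partition) -> list[SequenceRecord]:
        return [r for r in self.records if r.partition is partition]

    @property
    def id_records(self) -> list[SequenceRecord]:
        return self.partition_records(Partition.ID)

    @property
    def ood_records(self) -> list[SequenceRecord]:
        return self.partition_records(Partition.OOD)

    def subset(self, predicate: Callable[[SequenceRecord], bool]) -> "GenusDataset":
        return GenusDataset(
            [r for r in self.records if predicate(r)], self.metadata, validate=False
        )

    def replace_records(self, records: Sequence[SequenceRecord]) -> "GenusDataset":
        return GenusDataset(records, self.metadata)

    def encode(self) -> np.ndarray:
        """Numeric base codes, shape (n, L); non-ACGT letters are 255."""
        return encode_codes(r.sequence for r in self.records)


@dataclass
class SplitDataset:
    """70/30-style split of the ID records, with OOD records passed through.

    ``classes`` is the fixed, ordered list of ID species names used as the
    classifier's label space; OOD species never appear in it.
    """

    train_id: list[SequenceRecord]
    test_id: list[SequenceRecord]
    ood: list[SequenceRecord]
    classes: list[str]

    def __post_init__(self) -> None:
        train_ids = {r.sample_id for r in self.train_id}
        test_ids = {r.sample_id for r in self.test_id}
        if train_ids & test_ids:
            raise ValueError("train and test sets overlap")
        ood_species = {r.species for r in self.ood}
        if ood_species & set(self.classes):
            raise ValueError("OOD species present in the class list")

    @property
    def alignment_length(self) -> int:
        return len(self.train_id[0].sequence)

    def map_records(
        self, fn: Callable[[list[SequenceRecord]], list[SequenceRecord]]
    ) -> "SplitDataset":
        """Apply ``fn`` to each of the three record collections."""
        return SplitDataset(
            fn(self.train_id), fn(self.test_id), fn(self.ood), list(self.classes)
        )
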