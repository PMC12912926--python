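"""Dataset preparation for barcoding experiments.

Implements the preparation pipeline applied to every genus dataset before
training and evaluation: length filtering, capping of over-represented
species, the rare-species ID/OOD partition, "Small" database halving,
fragment-window extraction, sequencing-noise injection, one-hot encoding and
stratified train/test splitting, plus FASTA round-trip I/O.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from ._seeds import rng_for
from .dataset import GenusDataset, Partition, SequenceRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "filter_by_length",
    "cap_species",
    "split_id_ood",
    "make_small",
    "extract_window",
    "inject_noise",
    "one_hot",
    "one_hot_decode",
    "encode_one_hot",
    "train_test_split_id",
]

# One-hot column order: A, T, G, C.
ONEHOT_ORDER = "ATGC"
_ONEHOT_TABLE = np.zeros((256, 4), dtype=np.float32)
for _i, _b in enumerate(ONEHOT_ORDER):
    _ONEHOT_TABLE[ord(_b), _i] = 1.0
    _ONEHOT_TABLE[ord(_b.lower()), _i] = 1.0


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def _parse_header(header: str) -> tuple[str, dict[str, str]]:
    parts = header.split("|")
    fields = {}
    for part in parts[1:]:
        if "=" in part:
            key, value = part.split("=", 1)
            fields[key] = value
    return parts[0], fields


def read_fasta(path, species_table: dict[str, str] | None = None) -> GenusDataset:
    """Read an aligned FASTA into a :class:`GenusDataset`.

    Species labels are taken from the ``|species=NAME`` header convention or,
    if absent, from ``species_table`` mapping sample id to species. A
    ``|partition=ID`` field restores a previously assigned partition.
    """
    records = []
    for bio in SeqIO.parse(str(path), "fasta"):
        sample_id, fields = _parse_header(bio.id + bio.description[len(bio.id):])
        sample_id = sample_id.strip()
        species = fields.get("species")
        if species is None and species_table is not None:
            species = species_table.get(sample_id)
        if species is None:
            raise ValueError(f"no species label for record {sample_id!r}")
        partition = Partition(fields.get("partition", "UNASSIGNED"))
        records.append(
            SequenceRecord(sample_id, species, str(bio.seq).upper(), partition)
        )
    return GenusDataset(records, metadata={"source": str(path)})


def write_fasta(dataset: GenusDataset, path) -> None:
    """Write a dataset with the ``>id|species=...|partition=...`` header convention."""
    origin = dataset.metadata.get("origin", "data")
    bio_records = [
        BioSeqRecord(
            Seq(rec.sequence),
            id=f"{rec.sample_id}|species={rec.species}|partition={rec.partition.value}|origin={origin}",
            description="",
        )
        for rec in dataset.records
    ]
    SeqIO.write(bio_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Filtering and partitioning
# ---------------------------------------------------------------------------

def filter_by_length(
    dataset: GenusDataset, min_len: int = 400, max_len: int = 1000
) -> GenusDataset:
    """Keep records whose ungapped length is strictly between the bounds."""
    return dataset.subset(lambda r: min_len < r.ungapped_length < max_len)


def cap_species(dataset: GenusDataset, cap: int = 125, seed: int = 0) -> GenusDataset:
    """Randomly subsample species with more than ``cap`` records down to ``cap``."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    counts = dataset.species_counts()
    keep: set[str] = set()
    for species, n in sorted(counts.items()):
        ids = [r.sample_id for r in dataset.records_of(species)]
        if n > cap:
            rng = rng_for(seed, "cap", species)
            ids = list(rng.choice(ids, size=cap, replace=False))
        keep.update(ids)
    return dataset.subset(lambda r: r.sample_id in keep)


def split_id_ood(dataset: GenusDataset, min_n: int = 15) -> GenusDataset:
    """Assign species with at least ``min_n`` records to ID, the rest to OOD."""
    counts = dataset.species_counts()
    if not any(n >= min_n for n in counts.values()):
        raise ValueError(
            f"degenerate dataset: no species reaches {min_n} samples, "
            "nothing is trainable"
        )
    if all(n >= min_n for n in counts.values()):
        warnings.warn("all species meet the ID sample-size bar; OOD set is empty")
    records = [
        r.with_partition(
            Partition.ID if counts[r.species] >= min_n else Partition.OOD
        )
        for r in dataset.records
    ]
    return dataset.replace_records(records)


def make_small(dataset: GenusDataset, floor: int = 5, seed: int = 0) -> GenusDataset:
    """Randomly halve each species, keeping at least ``floor`` records per ID species.

    Emulates the reduced-database condition: per ID species retain
    ``max(floor, ceil(n/2))`` records (never more than available); OOD
    species are halved with a floor of one.
    """
    counts = dataset.species_counts()
    keep: set[str] = set()
    for species in sorted(counts):
        recs = dataset.records_of(species)
        n = len(recs)
        is_id = recs[0].partition is Partition.ID
        n_keep = min(n, max(floor if is_id else 1, math.ceil(n / 2)))
        rng = rng_for(seed, "small", species)
        ids = [r.sample_id for r in recs]
        keep.update(rng.choice(ids, size=n_keep, replace=False))
    return dataset.subset(lambda r: r.sample_id in keep)


# ---------------------------------------------------------------------------
# Fragments and noise
# ---------------------------------------------------------------------------

def extract_window(dataset: GenusDataset, start: int, end: int) -> GenusDataset:
    """Slice every sequence to the 0-based half-open window [start, end)."""
    length = dataset.alignment_length
    if not (0 <= start < end <= length):
        raise ValueError(f"invalid window [{start}, {end}) for alignment length {length}")
    if (start, end) == (0, length):
        return dataset
    return dataset.replace_records(
        [r.with_sequence(r.sequence[start:end]) for r in dataset.records]
    )


def inject_noise(
    dataset: GenusDataset, rate: float = 0.02, seed: int = 0, mode: str = "exact"
) -> GenusDataset:
    """Substitute random bases per fragment with random alternatives.

    With ``mode='exact'`` exactly ``round(rate * L)`` distinct canonical-base
    positions per fragment are selected uniformly; with ``mode='bernoulli'``
    every canonical position is hit independently with probability ``rate``
    (per-fragment noise load varies, as with real sequencing error). In both
    modes the base is replaced by one of its three alternatives with
    probability 1/3, so the replacement always differs from the original, and
    non-ACGT positions are never touched. Emulates sequencing error on test
    material; training references stay clean.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("noise rate must be in [0, 1]")
    if mode not in ("exact", "bernoulli"):
        raise ValueError("mode must be 'exact' or 'bernoulli'")
    if not dataset.records:
        return dataset
    length = dataset.alignment_length
    n_swap = round(rate * length)
    if mode == "exact" and n_swap == 0:
        if rate > 0:
            warnings.warn(
                f"noise rate {rate} on length {length} rounds to zero changes"
            )
        return dataset
    rng = rng_for(seed, "noise")
    alphabet = "ACGT"
    out = []
    for rec in dataset.records:
        seq = list(rec.sequence)
        canonical = [i for i, c in enumerate(seq) if c in alphabet]
        if mode == "exact":
            k = min(n_swap, len(canonical))
            positions = rng.choice(canonical, size=k, replace=False)
        else:
            hits = rng.random(len(canonical)) < rate
            positions = [p for p, h in zip(canonical, hits) if h]
        for pos in positions:
            choices = [b for b in alphabet if b != seq[pos]]
            seq[pos] = choices[rng.integers(3)]
        out.append(rec.with_sequence("".join(seq)))
    return dataset.replace_records(out)


# ---------------------------------------------------------------------------
# Encoding and splitting
# ---------------------------------------------------------------------------

def one_hot(sequence: str) -> np.ndarray:
    """Encode a sequence as an (L, 4) one-hot matrix with column order A, T, G, C.

    Noncanonical letters (ambiguity codes, gaps) map to the all-zero row.
    """
    buf = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _ONEHOT_TABLE[buf].copy()


def one_hot_decode(matrix: np.ndarray) -> str:
    """Inverse of :func:`one_hot` on canonical rows; zero rows decode to 'N'."""
    letters = []
    for row in matrix:
        if row.sum() == 0:
            letters.append("N")
        else:
            letters.append(ONEHOT_ORDER[int(np.argmax(row))])
    return "".join(letters)


def encode_one_hot(records: Iterable[SequenceRecord]) -> np.ndarray:
    """Stack one-hot matrices for a record collection, shape (n, L, 4)."""
    mats = [one_hot(r.sequence) for r in records]
    return np.stack(mats) if mats else np.empty((0, 0, 4), dtype=np.float32)


def train_test_split_id(
    dataset: GenusDataset, train_frac: float = 0.7, seed: int = 0
):
    """Stratified per-species split of the ID records; OOD passes through.

    Per ID species the train count is ``round(train_frac * n)`` clamped so
    both sides keep at least one record.
    """
    from .dataset import SplitDataset

    id_records = dataset.id_records
    if not id_records:
        raise ValueError("no ID records to split; assign partitions first")
    classes = sorted({r.species for r in id_records})
    train, test = [], []
    for species in classes:
        recs = [r for r in id_records if r.species == species]
        n = len(recs)
        if n < 2:
            raise ValueError(
                f"ID species {species!r} has a single record; cannot stratify"
            )
        n_train = int(np.clip(math.floor(train_frac * n + 0.5), 1, n - 1))
        rng = rng_for(seed, "split", species)
        order = rng.permutation(n)
        train.extend(recs[i] for i in sorted(order[:n_train]))
        test.extend(recs[i] for i in sorted(order[n_train:]))
    return SplitDataset(train, test, dataset.ood_records, classes)
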