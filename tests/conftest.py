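import numpy as np
import pytest

from barcodeood.dataset import GenusDataset, Partition, SequenceRecord
from barcodeood.syndata import SimParams, simulate_genus, star_tree


def make_dataset(spec: dict[str, int], length: int = 60, seed: int = 0,
                 partition: bool = False) -> GenusDataset:
    """Toy dataset: ``spec`` maps species name -> record count.

    Sequences are random but conspecific records share a base haplotype with
    one private substitution each, so species are trivially separable.
    """
    rng = np.random.default_rng(seed)
    records = []
    for species, n in spec.items():
        base = rng.choice(list("ACGT"), size=length)
        for i in range(n):
            seq = base.copy()
            pos = int(rng.integers(length))
            seq[pos] = "ACGT"[(("ACGT".index(seq[pos])) + 1) % 4]
            part = Partition.UNASSIGNED
            if partition:
                part = Partition.ID if n >= 15 else Partition.OOD
            records.append(
                SequenceRecord(f"{species}_{i:03d}", species, "".join(seq), part)
            )
    return GenusDataset(records)


@pytest.fixture(scope="session")
def separable_genus() -> GenusDataset:
    """Well-separated synthetic genus: star tree, tiny within-species distance."""
    params = SimParams(
        n_species=8,
        mean_samples_per_species=25,
        target_dw=0.002,
        tree_height=0.05,
        seq_length=300,
        seed=3,
    )
    return simulate_genus(params, tree=star_tree(8, 0.05))


@pytest.fixture(scope="session")
def trained_separable(separable_genus):
    """A small CNN trained once on the separable genus (shared across tests)."""
    from barcodeood import cnn
    from barcodeood.seqprep import train_test_split_id

    split = train_test_split_id(separable_genus, seed=1)
    spec = cnn.CnnSpec(n_classes=len(split.classes), input_length=300)
    model = cnn.build_model(spec, split.classes, seed=0)
    cnn.train(model, split.train_id, epochs=12)
    return model, split
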