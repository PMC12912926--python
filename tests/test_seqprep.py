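import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barcodeood import seqprep
from barcodeood.dataset import GenusDataset, Partition, SequenceRecord

from conftest import make_dataset


class TestFastaIO:
    def test_round_trip_is_identity(self, tmp_path):
        ds = make_dataset({"alpha": 2, "beta": 3}, length=40)
        ds = seqprep.split_id_ood(ds, min_n=3)
        path = tmp_path / "toy.fasta"
        seqprep.write_fasta(ds, path)
        back = seqprep.read_fasta(path)
        assert back.records == ds.records

    def test_species_parsed_from_header(self, tmp_path):
        path = tmp_path / "two.fasta"
        path.write_text(">s1|species=alpha\nACGT\n>s2|species=beta\nACGA\n")
        ds = seqprep.read_fasta(path)
        assert [r.species for r in ds.records] == ["alpha", "beta"]

    def test_missing_species_label_raises(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">s1\nACGT\n")
        with pytest.raises(ValueError, match="species"):
            seqprep.read_fasta(path)

    def test_sidecar_species_table(self, tmp_path):
        path = tmp_path / "plain.fasta"
        path.write_text(">s1\nACGT\n")
        ds = seqprep.read_fasta(path, species_table={"s1": "alpha"})
        assert ds.records[0].species == "alpha"

    def test_length_mismatch_raises(self, tmp_path):
        path = tmp_path / "ragged.fasta"
        path.write_text(">s1|species=a\nACGTACGTAC\n>s2|species=a\nACGTACGTA\n")
        with pytest.raises(ValueError, match="length"):
            seqprep.read_fasta(path)


class TestFilterAndPartition:
    def test_length_filter_bounds_are_strict(self):
        recs = [
            SequenceRecord("a", "x", "A" * 400),
            SequenceRecord("b", "x", "A" * 401),
            SequenceRecord("c", "x", "A" * 650),
            SequenceRecord("d", "x", "A" * 1000),
        ]
        ds = GenusDataset(recs, validate=False)
        kept = {r.sample_id for r in seqprep.filter_by_length(ds)}
        assert kept == {"b", "c"}

    def test_length_filter_uses_ungapped_length(self):
        rec = SequenceRecord("a", "x", "A" * 398 + "--")
        ds = GenusDataset([rec], validate=False)
        assert len(seqprep.filter_by_length(ds)) == 0

    def test_filter_empty_dataset(self):
        assert len(seqprep.filter_by_length(GenusDataset([]))) == 0

    @pytest.mark.parametrize("n,expected", [(130, 125), (125, 125), (10, 10)])
    def test_cap_species(self, n, expected):
        ds = make_dataset({"big": n})
        assert len(seqprep.cap_species(ds, cap=125, seed=1)) == expected

    def test_cap_is_seed_deterministic(self):
        ds = make_dataset({"big": 140, "small": 5})
        a = seqprep.cap_species(ds, seed=7)
        b = seqprep.cap_species(ds, seed=7)
        assert a.records == b.records

    @pytest.mark.parametrize("n,part", [(15, Partition.ID), (14, Partition.OOD)])
    def test_id_ood_boundary(self, n, part):
        ds = make_dataset({"focal": n, "anchor": 20})
        out = seqprep.split_id_ood(ds, min_n=15)
        assert all(r.partition is part for r in out.records_of("focal"))

    def test_no_ood_species_warns(self):
        ds = make_dataset({"a": 20, "b": 18})
        with pytest.warns(UserWarning, match="OOD set is empty"):
            seqprep.split_id_ood(ds, min_n=15)

    def test_degenerate_dataset_raises(self):
        ds = make_dataset({"a": 3, "b": 4})
        with pytest.raises(ValueError, match="degenerate"):
            seqprep.split_id_ood(ds, min_n=15)

    def test_split_then_cap_idempotent(self):
        ds = make_dataset({"a": 130, "b": 20, "c": 4})
        once = seqprep.split_id_ood(seqprep.cap_species(ds, seed=1), min_n=15)
        twice = seqprep.split_id_ood(seqprep.cap_species(once, seed=1), min_n=15)
        assert once.records == twice.records


class TestMakeSmall:
    @pytest.mark.parametrize("n,expected", [(40, 20), (15, 8), (8, 5)])
    def test_id_species_halved_with_floor(self, n, expected):
        ds = make_dataset({"focal": n, "anchor": 20})
        recs = [r.with_partition(Partition.ID) for r in ds.records]
        small = seqprep.make_small(GenusDataset(recs), floor=5, seed=0)
        assert len(small.records_of("focal")) == expected

    def test_ood_species_floor_is_one(self):
        ds = make_dataset({"rare": 1, "anchor": 20})
        recs = [
            r.with_partition(Partition.OOD if r.species == "rare" else Partition.ID)
            for r in ds.records
        ]
        small = seqprep.make_small(GenusDataset(recs), seed=0)
        assert len(small.records_of("rare")) == 1


class TestWindowAndNoise:
    def test_window_lengths_match_contract(self):
        ds = make_dataset({"a": 2}, length=650)
        assert seqprep.extract_window(ds, 350, 650).alignment_length == 300
        assert seqprep.extract_window(ds, 350, 500).alignment_length == 150

    def test_full_window_is_identity(self):
        ds = make_dataset({"a": 2}, length=650)
        assert seqprep.extract_window(ds, 0, 650) is ds

    def test_invalid_window_raises(self):
        ds = make_dataset({"a": 2}, length=650)
        with pytest.raises(ValueError):
            seqprep.extract_window(ds, 500, 400)

    @pytest.mark.parametrize("length,expected", [(650, 13), (300, 6), (150, 3)])
    def test_exact_noise_count_scales_with_fragment(self, length, expected):
        ds = make_dataset({"a": 5}, length=length)
        noisy = seqprep.inject_noise(ds, rate=0.02, seed=1)
        for before, after in zip(ds.records, noisy.records):
            diffs = sum(x != y for x, y in zip(before.sequence, after.sequence))
            assert diffs == expected

    def test_zero_rate_is_identity(self):
        ds = make_dataset({"a": 3}, length=100)
        assert seqprep.inject_noise(ds, rate=0.0, seed=1).records == ds.records

    def test_sub_half_position_rate_warns_and_is_identity(self):
        ds = make_dataset({"a": 1}, length=20)
        with pytest.warns(UserWarning, match="zero changes"):
            out = seqprep.inject_noise(ds, rate=0.02, seed=1)
        assert out.records == ds.records

    def test_noise_never_touches_ambiguous_positions(self):
        rec = SequenceRecord("a", "x", "N" * 10 + "A" * 90)
        ds = GenusDataset([rec])
        noisy = seqprep.inject_noise(ds, rate=0.05, seed=2)
        assert noisy.records[0].sequence[:10] == "N" * 10

    def test_alternative_bases_uniform(self):
        # replacements of 'A' should hit C/G/T each ~1/3 of the time
        ds = GenusDataset(
            [SequenceRecord(f"s{i}", "x", "A" * 100) for i in range(200)]
        )
        noisy = seqprep.inject_noise(ds, rate=0.1, seed=3)
        counts = {"C": 0, "G": 0, "T": 0}
        for rec in noisy.records:
            for c in rec.sequence:
                if c != "A":
                    counts[c] += 1
        total = sum(counts.values())
        assert total == 200 * 10
        se = np.sqrt(total * (1 / 3) * (2 / 3))
        for c in counts.values():
            assert abs(c - total / 3) < 3 * se

    def test_bernoulli_mode_mean_rate(self):
        ds = GenusDataset(
            [SequenceRecord(f"s{i}", "x", "A" * 200) for i in range(100)]
        )
        noisy = seqprep.inject_noise(ds, rate=0.02, seed=4, mode="bernoulli")
        diffs = [
            sum(c != "A" for c in rec.sequence) for rec in noisy.records
        ]
        assert 0.015 < np.mean(diffs) / 200 < 0.025
        assert np.std(diffs) > 0  # per-fragment load varies


class TestOneHot:
    def test_published_rows(self):
        np.testing.assert_array_equal(
            seqprep.one_hot("AT"), [[1, 0, 0, 0], [0, 1, 0, 0]]
        )

    def test_noncanonical_letters_zero_row(self):
        for letter in "NRY-":
            assert seqprep.one_hot(letter).sum() == 0

    @given(st.text(alphabet="ACGT", min_size=1, max_size=80))
    @settings(max_examples=50, deadline=None)
    def test_decode_inverts_encode_on_canonical(self, seq):
        assert seqprep.one_hot_decode(seqprep.one_hot(seq)) == seq

    def test_rows_sum_to_zero_or_one(self):
        m = seqprep.one_hot("ACGTNRY-WA")
        sums = m.sum(axis=1)
        assert set(sums.tolist()) <= {0.0, 1.0}


class TestTrainTestSplit:
    def test_stratified_counts(self):
        ds = make_dataset({"a": 20, "b": 16}, seed=5)
        ds = seqprep.split_id_ood(ds, min_n=15)
        split = seqprep.train_test_split_id(ds, train_frac=0.7, seed=0)
        a_train = sum(r.species == "a" for r in split.train_id)
        assert a_train == 14  # round(0.7 * 20)

    def test_disjoint_and_covering(self):
        ds = make_dataset({"a": 20, "b": 16, "rare": 3}, seed=5)
        ds = seqprep.split_id_ood(ds, min_n=15)
        split = seqprep.train_test_split_id(ds, seed=0)
        train_ids = {r.sample_id for r in split.train_id}
        test_ids = {r.sample_id for r in split.test_id}
        assert not train_ids & test_ids
        assert train_ids | test_ids == {r.sample_id for r in ds.id_records}
        assert {r.species for r in split.ood} == {"rare"}

    def test_every_class_in_both_sides(self):
        ds = make_dataset({"a": 15, "b": 15}, seed=2)
        ds = seqprep.split_id_ood(ds, min_n=15)
        split = seqprep.train_test_split_id(ds, seed=3)
        for side in (split.train_id, split.test_id):
            assert {r.species for r in side} == {"a", "b"}

    def test_seed_determinism(self):
        ds = seqprep.split_id_ood(make_dataset({"a": 20, "b": 16}), min_n=15)
        s1 = seqprep.train_test_split_id(ds, seed=9)
        s2 = seqprep.train_test_split_id(ds, seed=9)
        assert s1.train_id == s2.train_id and s1.test_id == s2.test_id

    def test_singleton_id_species_raises(self):
        recs = [
            SequenceRecord("a1", "a", "ACGT", Partition.ID),
            SequenceRecord("b1", "b", "ACGT", Partition.ID),
            SequenceRecord("b2", "b", "ACGA", Partition.ID),
        ]
        with pytest.raises(ValueError, match="single record"):
            seqprep.train_test_split_id(GenusDataset(recs), seed=0)
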