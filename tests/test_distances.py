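import math

import numpy as np
import pytest

from barcodeood import distances as D
from barcodeood.dataset import GenusDataset, Partition, SequenceRecord
from barcodeood.seqprep import split_id_ood, train_test_split_id
from barcodeood.syndata import SimParams, sample_individuals, star_tree, evolve_species_consensus

from conftest import make_dataset


def k2p_oracle(a: str, b: str) -> float:
    """Independent site-counting + closed-form oracle."""
    ts_pairs = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    valid = ts = tv = 0
    for x, y in zip(a, b):
        if x in "ACGT" and y in "ACGT":
            valid += 1
            if x != y:
                if (x, y) in ts_pairs:
                    ts += 1
                else:
                    tv += 1
    P, Q = ts / valid, tv / valid
    if 1 - 2 * P - Q <= 0 or 1 - 2 * Q <= 0:
        return math.inf
    return -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)


class TestK2P:
    def test_identical_sequences_zero(self):
        assert D.k2p_distance("ACGT" * 25, "ACGT" * 25) == 0.0

    def test_worked_value(self):
        # 10 transitions + 5 transversions over 100 sites: P=0.1, Q=0.05
        a = "A" * 100
        b = "G" * 10 + "C" * 5 + "A" * 85
        assert D.k2p_distance(a, b) == pytest.approx(0.170181, abs=5e-7)

    def test_saturated_pair_is_inf(self):
        # P=0.5, Q=0: log argument hits zero
        a = "A" * 100
        b = "G" * 50 + "A" * 50
        assert D.k2p_distance(a, b) == math.inf

    def test_matches_site_counting_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            a = "".join(rng.choice(list("ACGT"), 200))
            mask = rng.random(200) < 0.1
            b = "".join(
                "ACGT"[(("ACGT".index(c)) + int(rng.integers(1, 4))) % 4] if m else c
                for c, m in zip(a, mask)
            )
            expected = k2p_oracle(a, b)
            assert D.k2p_distance(a, b) == pytest.approx(expected, abs=1e-12)

    def test_pairwise_deletion(self):
        a = "NNAAA"
        b = "AAGAA"
        # only 3 jointly canonical sites, 1 transition
        assert D.k2p_distance(a, b, min_overlap=0.0) == pytest.approx(
            k2p_oracle(a, b), abs=1e-12
        )

    def test_low_overlap_flagged_nan(self):
        assert math.isnan(D.k2p_distance("NNNA", "AAAA"))

    def test_zero_overlap_raises(self):
        with pytest.raises(ValueError, match="canonical"):
            D.k2p_distance("NNNN", "AAAA")

    def test_matrix_agrees_with_scalar_and_is_symmetric(self):
        rng = np.random.default_rng(1)
        seqs = ["".join(rng.choice(list("ACGT"), 120)) for _ in range(8)]
        ds = GenusDataset(
            [SequenceRecord(f"s{i}", "x", s) for i, s in enumerate(seqs)]
        )
        mat = D.k2p_matrix(ds)
        assert np.allclose(mat, mat.T)
        assert np.all(np.diag(mat) == 0)
        for i in range(8):
            for j in range(i + 1, 8):
                assert mat[i, j] == pytest.approx(
                    D.k2p_distance(seqs[i], seqs[j]), abs=1e-9
                )


class TestPercentIdentity:
    def test_identical(self):
        assert D.percent_identity("ACGT" * 10, "ACGT" * 10) == 100.0

    def test_single_interior_mismatch(self):
        a = "A" * 50 + "C" * 50
        b = a[:50] + "G" + a[51:]
        assert D.percent_identity(a, b) == pytest.approx(99.0)

    def test_two_bp_insertion_matches_dp_oracle(self):
        # aperiodic sequence so the gapped alignment is the unique optimum
        a = "ACCGTTAGGACTTGCACAAG"
        b = a[:10] + "GG" + a[10:]
        # alignment: 20 matches + 2-bp gap = 22 columns
        assert D.percent_identity(a, b) == pytest.approx(100 * 20 / 22)

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError, match="empty"):
            D.percent_identity("", "ACGT")

    def test_batch_kernel_matches_scalar(self):
        rng = np.random.default_rng(3)
        qs = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(5)]
        rs = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(5)]
        batch = D._identity_distance_cross(qs, rs)
        for i, q in enumerate(qs):
            for j, r in enumerate(rs):
                assert batch[i, j] == pytest.approx(
                    (100.0 - D.percent_identity(q, r)) / 100.0, abs=1e-12
                )


def _recs(seqs, species=None, ids=None):
    return [
        SequenceRecord(
            ids[i] if ids else f"s{i}", species[i] if species else "x", s
        )
        for i, s in enumerate(seqs)
    ]


class TestNearestNeighbor:
    def test_identical_query_distance_zero(self):
        refs = _recs(["AAAA", "CCCC"], species=["a", "b"])
        label, dist = D.nn_classify(SequenceRecord("q", "?", "CCCC"), refs)
        assert (label, dist) == ("b", 0.0)

    def test_closest_reference_wins(self):
        refs = _recs(["AAAAAAAAAA", "GGGGAAAAAA"], species=["near", "far"])
        query = SequenceRecord("q", "?", "GAAAAAAAAA")
        label, _ = D.nn_classify(query, refs)
        assert label == "near"

    def test_tie_breaks_to_smallest_sample_id(self):
        refs = _recs(
            ["GAAA", "GAAA"], species=["late", "early"], ids=["zz", "aa"]
        )
        label, dist = D.nn_classify(SequenceRecord("q", "?", "AAAA"), refs)
        assert label == "early"


class TestThresholds:
    def test_constant_minima(self):
        # two haplotypes at fixed distance: all LOO minima equal
        refs = _recs(["A" * 99 + "G"] * 10 + ["A" * 100] * 10, ["x"] * 20)
        thr = D.distance_thresholds(refs, q=0.95)
        assert thr["x"] == pytest.approx(0.0)

    def test_type7_quantile_of_spread_minima(self):
        vals = np.array([0.0, 0.01, 0.02, 0.03])
        assert D._quantile(vals, 0.95) == pytest.approx(np.quantile(vals, 0.95))

    def test_singleton_class_warns_inf(self):
        refs = _recs(["AAAA", "CCCC", "CCCA"], species=["solo", "b", "b"])
        with pytest.warns(UserWarning, match="single reference"):
            thr = D.distance_thresholds(refs)
        assert thr["solo"] == math.inf

    def test_flag_boundary_is_strict(self):
        refs = _recs(["A" * 100] * 3, ["x"] * 3)
        thr = {"x": 0.05}
        far = SequenceRecord("q1", "?", "G" * 20 + "A" * 80)
        near = SequenceRecord("q2", "?", "A" * 100)
        labels, dist, flags = D.distance_ood_flag([far, near], refs, thr)
        assert flags.tolist() == [True, False]
        # exactly at threshold -> accepted
        labels, dist, flags = D.distance_ood_flag(
            [near], refs, {"x": 0.0}
        )
        assert not flags[0]

    def test_query_calibrated_thresholds_track_noise_scale(self):
        rng = np.random.default_rng(0)
        base = "".join(rng.choice(list("ACGT"), 200))
        refs = _recs([base] * 10, ["x"] * 10)
        noisy_queries = []
        for i in range(10):
            seq = list(base)
            for pos in rng.choice(200, size=4, replace=False):
                seq[pos] = "ACGT"[("ACGT".index(seq[pos]) + 1) % 4]
            noisy_queries.append(SequenceRecord(f"q{i}", "x", "".join(seq)))
        clean = D.query_calibrated_thresholds(refs, refs)["x"]
        noisy = D.query_calibrated_thresholds(noisy_queries, refs)["x"]
        assert noisy > clean


class TestPopGen:
    def test_completeness_arithmetic(self):
        spec = {f"id{i}": 15 for i in range(15)} | {f"ood{i}": 2 for i in range(5)}
        ds = split_id_ood(make_dataset(spec, length=80, seed=1), min_n=15)
        m = D.popgen_metrics(ds)
        assert m.completeness == pytest.approx(0.75)
        assert m.n_classes == 15
        assert m.dbt_min <= m.dbt_avg

    def test_two_monomorphic_species(self):
        a = "A" * 100
        b = "G" * 5 + "A" * 95
        recs = [SequenceRecord(f"a{i}", "a", a, Partition.ID) for i in range(3)]
        recs += [SequenceRecord(f"b{i}", "b", b, Partition.ID) for i in range(3)]
        m = D.popgen_metrics(GenusDataset(recs))
        d = D.k2p_distance(a, b)
        assert m.dw_avg == 0.0
        assert m.dbt_avg == pytest.approx(d)
        assert m.dbt_min == pytest.approx(d)

    def test_simulated_dw_recovery(self):
        tree = star_tree(4, 0.1)
        consensus = evolve_species_consensus(tree, seq_length=650, seed=5)
        params = SimParams(
            n_species=4, mean_samples_per_species=30, target_dw=0.01,
            seq_length=650, seed=5,
        )
        ds = sample_individuals(consensus, params, abundances={s: 30 for s in consensus})
        ds = split_id_ood(ds, min_n=15)
        m = D.popgen_metrics(ds)
        assert 0.007 <= m.dw_avg <= 0.013


class TestPerfectBounds:
    def _split(self, train, test, ood):
        classes = sorted({r.species for r in train})
        from barcodeood.dataset import SplitDataset

        return SplitDataset(train, test, ood, classes)

    def test_no_duplicates_gives_trivial_bounds(self):
        train = _recs(["AAAA", "CCCC"], ["a", "b"], ids=["t1", "t2"])
        test = _recs(["AAAG", "CCCA"], ["a", "b"], ids=["e1", "e2"])
        ood = _recs(["GGGG"], ["z"], ids=["o1"])
        b = D.perfect_bounds(self._split(train, test, ood))
        assert (b.accuracy_upper, b.fnr_lower) == (1.0, 0.0)

    def test_heterospecific_duplicate_forces_error(self):
        train = _recs(["AAAA", "CCCC"], ["a", "b"], ids=["t1", "t2"])
        # test sample of species b identical to an 'a' reference only
        test = _recs(["AAAA", "CCCA"], ["b", "b"], ids=["e1", "e2"])
        b = D.perfect_bounds(self._split(train, test, []))
        assert b.accuracy_upper == pytest.approx(0.5)

    def test_tie_rule_options(self):
        # test sample identical to both a conspecific and a heterospecific ref
        train = _recs(["AAAA", "AAAA"], ["a", "b"], ids=["t1", "t2"])
        test = _recs(["AAAA"], ["a"], ids=["e1"])
        split = self._split(train, test, [])
        assert D.perfect_bounds(split).accuracy_upper == 0.0  # strict default
        assert D.perfect_bounds(split, ties="identifiable").accuracy_upper == 1.0
        assert D.perfect_bounds(split, ties="half").accuracy_upper == 0.5

    def test_ood_zero_distance_fraction(self):
        train = _recs(["AAAA"], ["a"], ids=["t1"])
        test = _recs(["AAAG"], ["a"], ids=["e1"])
        ood = _recs(["AAAA", "GGGG"], ["z", "z"], ids=["o1", "o2"])
        b = D.perfect_bounds(self._split(train, test, ood))
        assert b.fnr_lower == pytest.approx(0.5)
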