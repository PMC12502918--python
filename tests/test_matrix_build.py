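"""Distances, nearest-neighbor ordering and the run-count identity."""

import gzip

import numpy as np
import pytest

from synclass import (
    ColumnOrder,
    SyncmerParams,
    build_kmer_set,
    decode_kmer,
    hamming_distance,
    naive_runs_total,
    nearest_neighbor_order,
    pairwise_distances,
)
from synclass.errors import ConfigurationError, InputError
from synclass.matrix_build import AssemblyKmerSet
from conftest import brute_force_kmer_set, kmer_set, write_fasta


def labels_of(sets, order):
    return [sets[i].label for i in order.permutation]


def test_build_kmer_set_deduplicates(tmp_path, k2_params):
    path = write_fasta(tmp_path / "a1.fasta", "a1", "AATCTAA")
    ks = build_kmer_set(path, params=k2_params)
    assert ks.label == "a1"
    assert sorted(decode_kmer(c, 2) for c in ks.codes) == ["AA", "AT", "CT", "TA", "TC"]
    assert ks.source_length == 7


def test_build_kmer_set_merges_records_and_reads_gzip(tmp_path, k2_params):
    path = tmp_path / "multi.fasta.gz"
    with gzip.open(path, "wt") as fh:
        fh.write(">chr1\nAATC\n>plasmid\nCCGC\n")
    ks = build_kmer_set(path, params=k2_params)
    expected = brute_force_kmer_set("AATC", 2) | brute_force_kmer_set("CCGC", 2)
    assert {decode_kmer(c, 2) for c in ks.codes} == expected


def test_build_kmer_set_errors_name_the_file(tmp_path, k2_params):
    missing = tmp_path / "nope.fasta"
    with pytest.raises(InputError, match="nope.fasta"):
        build_kmer_set(missing, params=k2_params)
    empty = tmp_path / "empty.fasta"
    empty.write_text("")
    with pytest.raises(InputError, match="no records"):
        build_kmer_set(empty, params=k2_params)


def test_n_only_sequence_warns_and_yields_empty_set(tmp_path, k2_params):
    path = write_fasta(tmp_path / "n.fasta", "n", "NNNNNNNN")
    with pytest.warns(UserWarning, match="no usable k-mers"):
        ks = build_kmer_set(path, params=k2_params)
    assert len(ks.codes) == 0


@pytest.mark.parametrize(
    "x,y,expected", [("a1", "a4", 3), ("a2", "a6", 12), ("a1", "a1", 0)]
)
def test_hamming_distance_examples(example_sets, x, y, expected):
    by_label = {s.label: s for s in example_sets}
    assert hamming_distance(by_label[x], by_label[y]) == expected


def test_hamming_distance_rejects_mismatched_params(example_sets):
    other = kmer_set("z", "ACGTACG", SyncmerParams(k=3, subsample_mode="none",
                                                   canonicalize=False))
    with pytest.raises(ConfigurationError):
        hamming_distance(example_sets[0], other)


def test_pairwise_distances_against_set_algebra(example_sets):
    d = pairwise_distances(example_sets).d
    assert np.array_equal(d, d.T)
    assert (np.diag(d) == 0).all()
    labels = [s.label for s in example_sets]
    idx = {l: i for i, l in enumerate(labels)}
    for (a, b), v in {("a1", "a4"): 3, ("a1", "a5"): 4, ("a2", "a4"): 4,
                      ("a3", "a6"): 4}.items():
        assert d[idx[a], idx[b]] == v


def test_pairwise_distances_degenerate_cases(example_sets):
    single = pairwise_distances(example_sets[:1])
    assert single.d.shape == (1, 1) and single.d[0, 0] == 0
    dup = pairwise_distances([example_sets[0], example_sets[0]])
    assert dup.d[0, 1] == 0


def test_triangle_inequality_random_triples():
    rng = np.random.default_rng(11)
    for _ in range(30):
        sets = [
            AssemblyKmerSet(f"s{i}", np.unique(rng.integers(0, 64, rng.integers(1, 30))),
                            0, None)
            for i in range(3)
        ]
        d01 = hamming_distance(sets[0], sets[1])
        d12 = hamming_distance(sets[1], sets[2])
        d02 = hamming_distance(sets[0], sets[2])
        assert d02 <= d01 + d12


def test_nearest_neighbor_reproduces_worked_example(example_sets):
    d = pairwise_distances(example_sets)
    order = nearest_neighbor_order(d, start_index=0)
    assert labels_of(example_sets, order) == ["a1", "a4", "a2", "a5", "a3", "a6"]


def test_nearest_neighbor_tie_break_and_singleton():
    from synclass.matrix_build import DistanceMatrix

    equal = DistanceMatrix(4, np.ones((4, 4), dtype=np.int64) - np.eye(4, dtype=np.int64))
    assert nearest_neighbor_order(equal, 2).permutation == [2, 0, 1, 3]
    one = DistanceMatrix(1, np.zeros((1, 1), dtype=np.int64))
    assert nearest_neighbor_order(one, 0).permutation == [0]


def test_naive_runs_worked_example(example_sets):
    identity = ColumnOrder(list(range(6)), 0)
    assert naive_runs_total(example_sets, identity, 16) == 55
    nn = nearest_neighbor_order(pairwise_distances(example_sets), 0)
    assert naive_runs_total(example_sets, nn, 16) == 39


def test_naive_runs_empty_set_and_consistency_error(example_sets):
    empty = [AssemblyKmerSet("e", np.empty(0, dtype=np.int64), 0, None)]
    assert naive_runs_total(empty, ColumnOrder([0], 0), 16) == 16
    with pytest.raises(ConfigurationError):
        naive_runs_total(example_sets, ColumnOrder(list(range(6)), 0), 3)


def _brute_force_run_count(sets, order, universe_rows):
    """Materialize the 0/1 matrix and count maximal runs row by row."""
    from synclass import nrle_encode

    mat = np.zeros((universe_rows, len(sets)), dtype=np.uint8)
    for col, i in enumerate(order.permutation):
        mat[sets[i].codes, col] = 1
    return sum(max(1, len(nrle_encode(row))) for row in mat)


def test_run_count_identity_on_random_instances():
    """The consecutive-Hamming-distance formula equals brute-force row-run
    counting of the materialized matrix."""
    rng = np.random.default_rng(5)
    universe = 4**3
    for _ in range(20):
        n = int(rng.integers(1, 9))
        sets = [
            AssemblyKmerSet(
                f"s{i}",
                np.unique(rng.integers(0, universe, rng.integers(0, 40))),
                0, None,
            )
            for i in range(n)
        ]
        perm = list(rng.permutation(n))
        order = ColumnOrder([int(p) for p in perm], int(perm[0]))
        assert naive_runs_total(sets, order, universe) == _brute_force_run_count(
            sets, order, universe
        )


def test_nn_not_worse_than_random_orders_on_average():
    rng = np.random.default_rng(17)
    nn_totals, random_totals = [], []
    for _ in range(20):
        n = 8
        sets = [
            AssemblyKmerSet(
                f"s{i}", np.unique(rng.integers(0, 256, 60)), 0, None
            )
            for i in range(n)
        ]
        d = pairwise_distances(sets)
        nn = nearest_neighbor_order(d, 0)
        nn_totals.append(naive_runs_total(sets, nn, 256))
        for _ in range(20):
            perm = [int(p) for p in rng.permutation(n)]
            random_totals.append(
                naive_runs_total(sets, ColumnOrder(perm, perm[0]), 256)
            )
    assert np.mean(nn_totals) <= np.mean(random_totals)
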