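"""Binomial significance model and read classification."""

import io
from fractions import Fraction

import numpy as np
import pytest

from synclass import (
    ClassifyOptions,
    SyncmerParams,
    binom_sf,
    build_pvalue_tables,
    classify_read,
    classify_stream,
    scale_matches,
)
from synclass.database import build_database_from_sets
from synclass.errors import ConfigurationError
from synclass.matrix_build import AssemblyKmerSet
from synclass.synthetic import mock_community
from conftest import kmer_set


def exact_binom_tail(n: int, p: Fraction, x: int) -> Fraction:
    """Big-rational upper-tail oracle."""
    from math import comb

    return sum(
        Fraction(comb(n, j)) * p**j * (1 - p) ** (n - j) for j in range(x, n + 1)
    )


def test_binom_sf_trivial_values():
    assert binom_sf(5, 0.7, 0) == 1.0
    assert binom_sf(1, 0.3, 1) == pytest.approx(0.3, rel=1e-15)
    assert binom_sf(2, 0.5, 1) == pytest.approx(0.75, rel=1e-15)
    assert binom_sf(4, 0.2, 5) == 0.0


def test_binom_sf_domain_errors():
    with pytest.raises(ValueError):
        binom_sf(5, 1.2, 1)
    with pytest.raises(ValueError):
        binom_sf(5, 0.5, 7)


@pytest.mark.parametrize("n", [1, 7, 19, 30])
def test_binom_sf_matches_rational_oracle(n):
    for tenths in range(1, 10):
        p = Fraction(tenths, 10)
        for x in range(n + 1):
            exact = float(exact_binom_tail(n, p, x))
            assert binom_sf(n, float(p), x) == pytest.approx(exact, rel=1e-12)


def test_binom_sf_is_stable_in_deep_tails():
    v = binom_sf(100, 1e-4, 50)
    assert 0 < v < 1e-150


def _tiny_db(sizes, universe=1000):
    params = SyncmerParams(k=4, subsample_mode="none", canonicalize=False)
    sets = [
        AssemblyKmerSet(f"s{i}", np.arange(sz, dtype=np.int64), 0, params)
        for i, sz in enumerate(sizes)
    ]
    return build_database_from_sets(sets, params=params, universe=universe)


def test_pvalue_tables_match_direct_evaluation():
    db = _tiny_db([100, 500])
    opts = ClassifyOptions(n_fixed=20)
    tables = build_pvalue_tables(db, opts)
    for col in range(2):
        p = db.set_sizes[col] / db.universe_size
        for x in range(21):
            assert tables.values[col, x] == pytest.approx(
                binom_sf(20, p, x), rel=1e-12, abs=5e-308
            )
    assert (tables.values[:, 0] == 1.0).all()
    assert (np.diff(tables.values, axis=1) <= 0).all()


def test_pvalue_table_degenerate_probabilities():
    # p=1: the tail is 1 everywhere in [0, n_fixed]
    db = _tiny_db([1000])
    tables = build_pvalue_tables(db, ClassifyOptions(n_fixed=10))
    assert (tables.values[0] == 1.0).all()


def test_pvalue_monotone_in_p():
    db = _tiny_db([10, 100, 400])
    tables = build_pvalue_tables(db, ClassifyOptions(n_fixed=50))
    # for fixed x > 0, larger p_i gives a larger tail
    for x in (1, 5, 25, 50):
        col_vals = tables.values[:, x]
        assert (np.diff(col_vals) >= 0).all()


@pytest.mark.parametrize(
    "x,n,n_fixed,expected",
    [(50, 200, 100, 25), (21, 21, 100, 21), (0, 150, 100, 0), (7, 100, 100, 7)],
)
def test_scale_matches(x, n, n_fixed, expected):
    assert scale_matches(x, n, n_fixed) == expected


def test_scale_matches_rejects_zero_trials():
    with pytest.raises(ValueError, match="unclassifiable"):
        scale_matches(0, 0, 100)


@pytest.fixture(scope="module")
def community_db():
    community = mock_community(2, 20_000, seed=42)
    params = SyncmerParams()  # defaults k=15, s=9, t=2, canonical syncmers
    sets = [kmer_set(l, s, params) for l, s in community.items()]
    db = build_database_from_sets(sets, params=params, universe=63_400_000)
    return community, db


def test_exact_substring_read_is_classified_correctly(community_db):
    community, db = community_db
    opts = ClassifyOptions()
    tables = build_pvalue_tables(db, opts)
    read = community["g001"][5000:7000]
    res = classify_read(db, tables, "r0", read, opts)
    assert res.status == "classified"
    assert res.label == "g001"
    assert res.p_value < opts.cutoff
    assert res.n >= 100  # a 2 kb read yields well over n_fixed trials


def test_too_short_and_non_matching_reads_are_unclassified(community_db):
    _, db = community_db
    opts = ClassifyOptions()
    tables = build_pvalue_tables(db, opts)
    short = classify_read(db, tables, "r1", "ACGTACGTACGTAC", opts)  # 14 < k
    assert short.status == "unclassified" and short.n == 0
    rng = np.random.default_rng(9)
    junk = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
    res = classify_read(db, tables, "r2", junk, opts)
    assert res.status == "unclassified"


def test_prefix_truncation_reduces_trials(community_db):
    community, db = community_db
    read = community["g000"][:3000]
    full = ClassifyOptions()
    cut = ClassifyOptions(max_read_length=360)
    t_full = build_pvalue_tables(db, full)
    n_full = classify_read(db, t_full, "r", read, full).n
    n_cut = classify_read(db, t_full, "r", read, cut).n
    assert n_cut <= n_full
    # trial count equals a brute-force window count on the truncated prefix
    from synclass import extract_kmers

    assert n_cut == len(extract_kmers(read[:360], db.params))


def test_threshold_monotonicity(community_db):
    """Raising the cutoff exponent never converts unclassified into
    classified."""
    community, db = community_db
    tables = build_pvalue_tables(db, ClassifyOptions())
    rng = np.random.default_rng(31)
    reads = ["".join("ACGT"[i] for i in rng.integers(0, 4, 300)) for _ in range(20)]
    reads += [community["g000"][100:400]]
    for seq in reads:
        lax = classify_read(db, tables, "r", seq, ClassifyOptions(cutoff_exponent=2))
        strict = classify_read(db, tables, "r", seq, ClassifyOptions(cutoff_exponent=12))
        if strict.status == "classified":
            assert lax.status == "classified"


def test_tables_nfixed_mismatch_rejected(community_db):
    _, db = community_db
    tables = build_pvalue_tables(db, ClassifyOptions(n_fixed=50))
    with pytest.raises(ConfigurationError):
        classify_read(db, tables, "r", "ACGT" * 30, ClassifyOptions(n_fixed=100))


def test_stream_format_independence_and_tsv_shape(tmp_path, community_db):
    community, db = community_db
    seqs = [("r1", community["g000"][:600]), ("r2", community["g001"][200:900]),
            ("r3", "ACGT" * 5)]
    fa = tmp_path / "reads.fasta"
    fa.write_text("".join(f">{rid}\n{s}\n" for rid, s in seqs))
    fq = tmp_path / "reads.fastq"
    fq.write_text("".join(f"@{rid}\n{s}\n+\n{'I' * len(s)}\n" for rid, s in seqs))

    out_fa, out_fq = io.StringIO(), io.StringIO()
    sum_fa = classify_stream(db, fa, ClassifyOptions(), out_fa)
    sum_fq = classify_stream(db, fq, ClassifyOptions(), out_fq)
    assert sum_fa == sum_fq
    assert out_fa.getvalue() == out_fq.getvalue()
    lines = out_fa.getvalue().strip().split("\n")
    assert lines[0].split("\t") == [
        "read_id", "status", "label", "p_value", "x_raw", "x_scaled", "n",
    ]
    assert len(lines) == 4  # header + one row per read, input order
    assert [l.split("\t")[0] for l in lines[1:]] == ["r1", "r2", "r3"]


def test_stream_empty_input(tmp_path, community_db):
    _, db = community_db
    empty = tmp_path / "empty.fastq"
    empty.write_text("")
    out = io.StringIO()
    summary = classify_stream(db, empty, ClassifyOptions(), out)
    assert summary == {"classified": 0, "unclassified": 0, "skipped": 0}
    assert out.getvalue().strip().split("\n")[-1].startswith("read_id")
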