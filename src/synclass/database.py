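"""Compressed, queryable k-mer x assembly reference database.

Construction pipeline: each reference FASTA becomes a deduplicated set of
canonical-syncmer codes (one matrix column); pairwise Hamming distances
feed the greedy nearest-neighbor heuristic to pick a run-minimizing column
order; each k-mer row of the permuted matrix is then adaptive-RLE encoded.
Only rows with at least one set bit are stored (absent codes mean zero
matches), indexed by sorted code for binary-search lookup.

The on-disk format is a small versioned binary layout, little-endian
throughout:

    magic "SKIMDB1\\0" | version u8 | k u8 | s u8 | t u8 | w u8 | flags u8
    | assembly count u32 | |U| u64 | length-prefixed (u16) UTF-8 labels in
    column order | |Ki| array u64 | row count u64 | row index of
    (code u64, word offset u64, word count u32) sorted by code
    | contiguous u16 word data

Flags: bit 0 = syncmer subsampling, bit 1 = canonicalize.
"""

from __future__ import annotations

import logging
import struct
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .arle import ARLERow, arle_encode, iter_set_bits, row_to_words, words_to_row
from .errors import ConfigurationError, FormatError
from .kmer_core import SyncmerParams, universe_size
from .matrix_build import (
    AssemblyKmerSet,
    ColumnOrder,
    build_kmer_set,
    nearest_neighbor_order,
    pairwise_distances,
)

__all__ = [
    "Database",
    "build_database",
    "query_kmer",
    "match_probability",
    "save_database",
    "load_database",
]

logger = logging.getLogger(__name__)

MAGIC = b"SKIMDB1\0"
VERSION = 1

# Monte-Carlo settings used when the universe is too large to enumerate.
MC_SAMPLES = 10**7
MC_SEED = 1
EXACT_UNIVERSE_MAX_K = 10


@dataclass
class Database:
    """Column-ordered, row-compressed k-mer presence matrix plus metadata.

    ``labels`` and ``set_sizes`` follow the permuted (M') column order;
    ``rows`` maps each k-mer code present in at least one assembly to its
    compressed row; ``universe_size`` is |U| for the stored parameters.
    """

    params: SyncmerParams
    w: int
    labels: list[str]
    set_sizes: np.ndarray  # |Ki| per column, int64
    universe_size: int
    rows: dict[int, ARLERow]
    order: ColumnOrder

    @property
    def n_assemblies(self) -> int:
        return len(self.labels)

    def equals(self, other: "Database") -> bool:
        """Field-by-field equality (used to verify save/load round trips)."""
        return (
            self.params == other.params
            and self.w == other.w
            and self.labels == other.labels
            and np.array_equal(self.set_sizes, other.set_sizes)
            and self.universe_size == other.universe_size
            and self.rows == other.rows
        )


def _default_universe(params: SyncmerParams) -> int:
    """|U|: exact enumeration for small k, cached Monte-Carlo otherwise.

    The match probabilities p_i = |Ki|/|U| only need a few significant
    digits for thresholding, so a 1e7-sample estimate is ample for large k.
    """
    if params.k <= EXACT_UNIVERSE_MAX_K:
        return int(universe_size(params, "exact").size)
    est = universe_size(params, "montecarlo", samples=MC_SAMPLES, seed=MC_SEED)
    return int(round(est.size))


def build_database(
    fasta_paths: Sequence[str | Path],
    params: SyncmerParams = SyncmerParams(),
    w: int = 16,
    start_index: int = 0,
    labels: Sequence[str] | None = None,
    distance_fn=None,
    universe: int | None = None,
) -> Database:
    """Build a compressed reference database from FASTA assemblies.

    One FASTA file is one classification target; labels default to the
    file stem and must be unique.  Deterministic given inputs, parameters
    and ``start_index``.
    """
    if not fasta_paths:
        raise ConfigurationError("at least one assembly is required")
    sets = []
    for i, path in enumerate(fasta_paths):
        label = labels[i] if labels is not None else None
        sets.append(build_kmer_set(path, label=label, params=params))
    return build_database_from_sets(
        sets, params=params, w=w, start_index=start_index,
        distance_fn=distance_fn, universe=universe,
    )


def build_database_from_sets(
    sets: Sequence[AssemblyKmerSet],
    params: SyncmerParams = SyncmerParams(),
    w: int = 16,
    start_index: int = 0,
    distance_fn=None,
    universe: int | None = None,
) -> Database:
    """Assemble a :class:`Database` from pre-built k-mer sets."""
    names = [s.label for s in sets]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ConfigurationError(f"duplicate assembly labels: {dupes}")
    for s in sets:
        if len(s) == 0:
            warnings.warn(
                f"assembly {s.label!r} has zero usable k-mers; its column is "
                "retained but its match probability is undefined"
            )

    dist = pairwise_distances(sets, distance_fn=distance_fn)
    order = nearest_neighbor_order(dist, start_index=start_index)
    perm = order.permutation
    ordered = [sets[i] for i in perm]
    n_cols = len(ordered)

    # Group (code, column) pairs by code and ARLE-encode each row bitmap.
    codes = np.concatenate([s.codes for s in ordered]) if ordered else np.empty(0)
    cols = np.concatenate(
        [np.full(len(s.codes), c, dtype=np.int64) for c, s in enumerate(ordered)]
    ) if ordered else np.empty(0, dtype=np.int64)
    sort = np.argsort(codes, kind="stable")
    codes, cols = codes[sort], cols[sort]

    rows: dict[int, ARLERow] = {}
    if len(codes):
        boundaries = np.flatnonzero(np.diff(codes)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(codes)]))
        bitmap = np.zeros(n_cols, dtype=np.uint8)
        for s_, e_ in zip(starts, ends):
            bitmap[:] = 0
            bitmap[cols[s_:e_]] = 1
            rows[int(codes[s_])] = arle_encode(bitmap, w)

    size = universe if universe is not None else _default_universe(params)
    return Database(
        params=params,
        w=w,
        labels=[s.label for s in ordered],
        set_sizes=np.array([len(s) for s in ordered], dtype=np.int64),
        universe_size=size,
        rows=rows,
        order=order,
    )


def query_kmer(db: Database, code: int) -> list[int]:
    """Column indices (in stored order) of assemblies containing a k-mer.

    Empty for codes absent from every assembly.  Time is proportional to
    the row's word count plus the number of set bits.
    """
    row = db.rows.get(int(code))
    if row is None:
        return []
    return list(iter_set_bits(row))


def match_probability(db: Database, column_index: int) -> float:
    """Per-assembly match probability p_i = |Ki| / |U|."""
    if db.universe_size <= 0:
        raise ConfigurationError("universe size must be positive")
    size = int(db.set_sizes[column_index])
    if size == 0:
        raise ConfigurationError(
            f"column {column_index} ({db.labels[column_index]!r}) is empty; "
            "its match probability is undefined"
        )
    return size / db.universe_size


# ---------------------------------------------------------------------------
# serialization

_FLAG_SYNCMER = 1
_FLAG_CANONICAL = 2


def save_database(db: Database, path: str | Path) -> None:
    """Write the database in the versioned binary layout (see module docs)."""
    p = db.params
    flags = (_FLAG_SYNCMER if p.subsample_mode == "syncmer" else 0) | (
        _FLAG_CANONICAL if p.canonicalize else 0
    )
    sorted_codes = sorted(db.rows)
    index = []
    word_values: list[int] = []
    offset = 0
    for code in sorted_codes:
        words = row_to_words(db.rows[code])
        index.append((code, offset, len(words)))
        word_values.extend(words)
        offset += len(words)

    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(struct.pack("<6B", VERSION, p.k, p.s, p.t, db.w, flags))
        fh.write(struct.pack("<I", len(db.labels)))
        fh.write(struct.pack("<Q", db.universe_size))
        for label in db.labels:
            raw = label.encode("utf-8")
            fh.write(struct.pack("<H", len(raw)))
            fh.write(raw)
        fh.write(np.asarray(db.set_sizes, dtype="<u8").tobytes())
        fh.write(struct.pack("<Q", len(index)))
        for code, off, cnt in index:
            fh.write(struct.pack("<QQI", code, off, cnt))
        fh.write(np.asarray(word_values, dtype="<u2").tobytes())


def _read_exact(fh, n: int, what: str) -> bytes:
    data = fh.read(n)
    if len(data) != n:
        raise FormatError(
            f"truncated database file while reading {what} at byte offset "
            f"{fh.tell() - len(data)}"
        )
    return data


def load_database(path: str | Path) -> Database:
    """Read a database written by :func:`save_database` (bit-exact inverse)."""
    with open(path, "rb") as fh:
        magic = _read_exact(fh, len(MAGIC), "magic")
        if magic != MAGIC:
            raise FormatError(f"{path} is not a recognized database file")
        version, k, s, t, w, flags = struct.unpack(
            "<6B", _read_exact(fh, 6, "header")
        )
        if version != VERSION:
            raise FormatError(f"unsupported database version {version}")
        mode = "syncmer" if flags & _FLAG_SYNCMER else "none"
        params = SyncmerParams(
            k=k,
            s=s,
            t=t,
            subsample_mode=mode,
            canonicalize=bool(flags & _FLAG_CANONICAL),
        )
        (n_cols,) = struct.unpack("<I", _read_exact(fh, 4, "assembly count"))
        (universe,) = struct.unpack("<Q", _read_exact(fh, 8, "universe size"))
        labels = []
        for _ in range(n_cols):
            (ln,) = struct.unpack("<H", _read_exact(fh, 2, "label length"))
            labels.append(_read_exact(fh, ln, "label").decode("utf-8"))
        set_sizes = np.frombuffer(
            _read_exact(fh, 8 * n_cols, "set sizes"), dtype="<u8"
        ).astype(np.int64)
        (n_rows,) = struct.unpack("<Q", _read_exact(fh, 8, "row count"))
        index = [
            struct.unpack("<QQI", _read_exact(fh, 20, "row index entry"))
            for _ in range(n_rows)
        ]
        total_words = sum(cnt for _, _, cnt in index)
        data = np.frombuffer(
            _read_exact(fh, 2 * total_words, "word data"), dtype="<u2"
        )
        if fh.read(1):
            raise FormatError(f"trailing data in database file {path}")

    rows = {
        int(code): words_to_row(data[off : off + cnt].tolist(), w, n_cols)
        for code, off, cnt in index
    }
    return Database(
        params=params,
        w=w,
        labels=labels,
        set_sizes=set_sizes,
        universe_size=int(universe),
        rows=rows,
        order=ColumnOrder(permutation=list(range(n_cols)), start_index=0),
    )


def write_manifest(
    db: Database, fasta_paths: Sequence[str | Path] | None, path: str | Path
) -> None:
    """Diagnostic TSV: label, source file, |Ki| and p_i per column."""
    files = {}
    if fasta_paths:
        for fp in fasta_paths:
            fp = Path(fp)
            files[fp.name.removesuffix(".gz").rsplit(".", 1)[0]] = str(fp)
    with open(path, "w") as fh:
        fh.write("label\tfile\tset_size\tmatch_probability\n")
        for i, label in enumerate(db.labels):
            size = int(db.set_sizes[i])
            p = size / db.universe_size if size else float("nan")
            fh.write(f"{label}\t{files.get(label, '-')}\t{size}\t{p:.6g}\n")
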