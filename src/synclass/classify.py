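"""Binomial-significance read classification against a reference database.

A read (or its first ℓ bases, emulating the chunk an adaptive-sampling
controller sees) is reduced to n canonical-syncmer queries.  Under the
null hypothesis that the read is random sequence, the number of queries
hitting assembly i is Bin(n, p_i) with p_i = |Ki|/|U|, so the upper-tail
probability P(Bin >= x_i) measures how surprising the observed match
count is.  To make a single cutoff comparable across read lengths, match
counts are rescaled to a fixed trial budget ``n_fixed`` (default 100):
x̄_i = floor(x_i * n_fixed / n) when n >= n_fixed, and x̄_i = x_i (no
scaling) for shorter reads; the P-value is always evaluated at n_fixed
trials from a precomputed per-assembly lookup table.  The read is assigned
to the assembly with the smallest P-value if that value is below 10**-e
(default e=12), otherwise it is reported unclassified.
"""

from __future__ import annotations

import gzip
import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
from scipy.stats import binom

from .arle import iter_set_bits
from .database import Database
from .errors import ConfigurationError, InputError
from .kmer_core import extract_kmers

__all__ = [
    "ClassifyOptions",
    "PValueTable",
    "ClassificationResult",
    "binom_sf",
    "build_pvalue_tables",
    "scale_matches",
    "classify_read",
    "classify_stream",
]

logger = logging.getLogger(__name__)

_TINY = sys.float_info.min  # smallest positive normal double


@dataclass(frozen=True)
class ClassifyOptions:
    """Classification knobs.

    ``n_fixed`` is the fixed binomial trial count of the P-value tables;
    ``cutoff_exponent`` e sets the significance threshold 10**-e;
    ``max_read_length`` ℓ truncates each read to its first ℓ bases
    (None = full read).
    """

    n_fixed: int = 100
    cutoff_exponent: float = 12.0
    max_read_length: int | None = None

    def __post_init__(self) -> None:
        if self.n_fixed < 1:
            raise ValueError("n_fixed must be >= 1")
        if self.cutoff_exponent <= 0:
            raise ValueError("cutoff_exponent must be > 0")

    @property
    def cutoff(self) -> float:
        return 10.0 ** (-self.cutoff_exponent)


@dataclass
class PValueTable:
    """Per-assembly upper-tail binomial tables.

    ``values[i, x] = P(Bin(n_fixed, p_i) >= x)`` for x in [0, n_fixed].
    Columns with undefined p_i (empty assemblies) are flagged in
    ``excluded`` and can never win.
    """

    n_fixed: int
    values: np.ndarray  # (n_columns, n_fixed + 1)
    p: np.ndarray  # p_i per column (0 where excluded)
    excluded: np.ndarray  # bool per column


@dataclass
class ClassificationResult:
    read_id: str
    status: str  # "classified" | "unclassified"
    label: str | None
    p_value: float
    x_raw: int
    x_scaled: int
    n: int


def binom_sf(n: int, p: float, x: int) -> float:
    """Exact upper tail P(Bin(n, p) >= x), stable down to ~1e-300.

    Defined for 0 <= x <= n + 1 with P(>=0) = 1 and P(>=n+1) = 0; computed
    through the regularized incomplete beta function.
    """
    if not (0 <= p <= 1):
        raise ValueError(f"p must be in [0, 1], got {p}")
    if n < 0 or not (0 <= x <= n + 1):
        raise ValueError(f"x={x} out of domain for n={n}")
    if x == 0:
        return 1.0
    if x == n + 1:
        return 0.0
    return float(binom.sf(x - 1, n, p))


def build_pvalue_tables(db: Database, options: ClassifyOptions) -> PValueTable:
    """Precompute P(Bin(n_fixed, p_i) >= x) for every column and x.

    Underflowed positive tails are clamped to the smallest positive normal
    double so that ordering among extreme winners stays defined; columns
    with |Ki| = 0 are excluded with a warning.
    """
    n_fixed = options.n_fixed
    n_cols = db.n_assemblies
    xs = np.arange(n_fixed + 1)
    values = np.empty((n_cols, n_fixed + 1))
    p = np.zeros(n_cols)
    excluded = np.zeros(n_cols, dtype=bool)
    for i in range(n_cols):
        size = int(db.set_sizes[i])
        if size == 0:
            excluded[i] = True
            values[i] = 1.0
            logger.warning(
                "assembly %r has no k-mers; excluded from classification",
                db.labels[i],
            )
            continue
        p[i] = size / db.universe_size
        sf = np.empty(n_fixed + 1)
        sf[0] = 1.0
        sf[1:] = binom.sf(xs[1:] - 1, n_fixed, p[i])
        if p[i] > 0:
            # keep strictly positive: the exact tail is positive whenever p>0
            sf = np.maximum(sf, _TINY)
        values[i] = sf
    return PValueTable(n_fixed=n_fixed, values=values, p=p, excluded=excluded)


def scale_matches(x: int, n: int, n_fixed: int) -> int:
    """Rescale a match count to the fixed trial budget.

    Returns floor(x * n_fixed / n) when n >= n_fixed; when fewer than
    n_fixed k-mers were queried the count is used unscaled (the P-value is
    still evaluated at n_fixed trials).
    """
    if n == 0:
        raise ValueError("no k-mer trials: read is unclassifiable")
    if not (0 <= x <= n):
        raise ValueError(f"match count x={x} out of range for n={n}")
    if n < n_fixed:
        return x
    return (x * n_fixed) // n


def classify_read(
    db: Database,
    tables: PValueTable,
    read_id: str,
    sequence: str,
    options: ClassifyOptions = ClassifyOptions(),
) -> ClassificationResult:
    """Classify one read against the database.

    Every emitted k-mer window counts as one trial (repeats included).
    The winner is the column with the smallest looked-up P-value; exact
    ties fall back to larger scaled count, then smaller p_i, then smaller
    column index.  Degenerate reads (no usable windows) are unclassified.
    """
    if tables.n_fixed != options.n_fixed:
        raise ConfigurationError(
            "P-value tables were built with a different n_fixed"
        )
    if options.max_read_length is not None:
        sequence = sequence[: options.max_read_length]
    codes = extract_kmers(sequence, db.params)
    n = len(codes)
    if n == 0:
        return ClassificationResult(read_id, "unclassified", None, 1.0, 0, 0, 0)

    x = np.zeros(db.n_assemblies, dtype=np.int64)
    for code in codes:
        row = db.rows.get(int(code))
        if row is not None:
            for col in iter_set_bits(row):
                x[col] += 1

    best = None  # (p_value, -x_scaled, p_i, col)
    for col in np.flatnonzero(x):
        if tables.excluded[col]:
            continue
        xs = scale_matches(int(x[col]), n, options.n_fixed)
        assert xs <= options.n_fixed
        pv = float(tables.values[col, xs])
        key = (pv, -xs, tables.p[col], int(col))
        if best is None or key < best:
            best = key
    if best is None:
        return ClassificationResult(read_id, "unclassified", None, 1.0, 0, 0, n)

    pv, neg_xs, _, col = best
    x_raw = int(x[col])
    if pv < options.cutoff:
        return ClassificationResult(
            read_id, "classified", db.labels[col], pv, x_raw, -neg_xs, n
        )
    return ClassificationResult(read_id, "unclassified", None, pv, x_raw, -neg_xs, n)


# ---------------------------------------------------------------------------
# streaming over read files


def _open_reads(path: str | Path) -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_format(fh: IO[str]) -> str | None:
    pos = fh.tell()
    first = fh.read(1)
    fh.seek(pos)
    if first == "":
        return None
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise InputError(f"unrecognized reads format (starts with {first!r})")


def iter_reads(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a FASTA or FASTQ file (.gz ok)."""
    from Bio import SeqIO

    with _open_reads(path) as fh:
        fmt = _sniff_format(fh)
        if fmt is None:
            return
        yield from ((rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, fmt))


def classify_stream(
    db: Database,
    reads: str | Path | Iterable[tuple[str, str]],
    options: ClassifyOptions = ClassifyOptions(),
    sink: IO[str] | None = None,
    header_comments: Iterable[str] = (),
) -> dict[str, int]:
    """Classify every read in a file or (id, sequence) iterable.

    Writes one TSV row per read (read_id, status, label, p_value, x_raw,
    x_scaled, n) in input order to ``sink`` when given, and returns
    summary counts per status.  Records that fail to parse are logged,
    counted under ``"skipped"`` and do not abort the stream.
    """
    summary = {"classified": 0, "unclassified": 0, "skipped": 0}
    tables = build_pvalue_tables(db, options)
    if sink is not None:
        for line in header_comments:
            sink.write(f"# {line}\n")
        sink.write("read_id\tstatus\tlabel\tp_value\tx_raw\tx_scaled\tn\n")

    if isinstance(reads, (str, Path)):
        source = iter_reads(reads)
    else:
        source = iter(reads)
    while True:
        try:
            item = next(source)
        except StopIteration:
            break
        except ValueError as exc:
            logger.warning("skipping malformed record: %s", exc)
            summary["skipped"] += 1
            continue
        read_id, seq = item
        res = classify_read(db, tables, read_id, seq, options)
        summary[res.status] += 1
        if sink is not None:
            label = res.label if res.label is not None else "-"
            sink.write(
                f"{res.read_id}\t{res.status}\t{label}\t{res.p_value:.6g}\t"
                f"{res.x_raw}\t{res.x_scaled}\t{res.n}\n"
            )
    logger.info(
        "classified %d, unclassified %d, skipped %d",
        summary["classified"], summary["unclassified"], summary["skipped"],
    )
    return summary
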