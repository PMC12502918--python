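"""Assembly k-mer sets, Hamming distances and run-minimizing column order.

Each reference assembly is reduced to the set of k-mer codes it contains
(a sparse representation of one column of the k-mer x assembly presence
matrix M).  The number of naive run-length-encoding runs needed to store
all rows of M equals the number of rows plus the sum of Hamming distances
between consecutive columns, so a column order that chains nearby columns
compresses better.  Finding the optimal order is NP-hard (it embeds
Hamiltonian path), so we use the greedy nearest-neighbor TSP heuristic.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from Bio import SeqIO

from .errors import ConfigurationError, InputError
from .kmer_core import SyncmerParams, extract_kmers

__all__ = [
    "AssemblyKmerSet",
    "DistanceMatrix",
    "ColumnOrder",
    "build_kmer_set",
    "hamming_distance",
    "pairwise_distances",
    "nearest_neighbor_order",
    "naive_runs_total",
]

logger = logging.getLogger(__name__)


@dataclass
class AssemblyKmerSet:
    """Sorted set of k-mer codes found in one reference assembly."""

    label: str
    codes: np.ndarray  # strictly increasing int64 codes
    source_length: int = 0
    params: SyncmerParams | None = None

    def __len__(self) -> int:
        return len(self.codes)


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise symmetric-difference sizes |Ki Δ Kj|."""

    n: int
    d: np.ndarray


@dataclass
class ColumnOrder:
    """A permutation of matrix columns and the heuristic's start column."""

    permutation: list[int]
    start_index: int = 0


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def build_kmer_set(
    fasta_path: str | Path,
    label: str | None = None,
    params: SyncmerParams = SyncmerParams(),
) -> AssemblyKmerSet:
    """Read a FASTA file (plain or gzipped) into a deduplicated k-mer set.

    Multi-record files (chromosomes, plasmids) merge into one set.  Raises
    :class:`InputError` for unreadable, empty or malformed files; warns if
    the assembly yields no usable k-mers (e.g. N-only sequence).
    """
    path = Path(fasta_path)
    if label is None:
        label = path.name.removesuffix(".gz").rsplit(".", 1)[0]
    chunks: list[np.ndarray] = []
    total = 0
    try:
        with _open_maybe_gzip(path) as fh:
            records = list(SeqIO.parse(fh, "fasta"))
    except OSError as exc:
        raise InputError(f"cannot read FASTA file {path}: {exc}") from exc
    except ValueError as exc:
        raise InputError(f"malformed FASTA file {path}: {exc}") from exc
    if not records:
        raise InputError(f"FASTA file {path} contains no records")
    for rec in records:
        seq = str(rec.seq)
        total += len(seq)
        codes = extract_kmers(seq, params)
        if len(codes):
            chunks.append(codes)
    if chunks:
        codes = np.unique(np.concatenate(chunks))
    else:
        codes = np.empty(0, dtype=np.int64)
        warnings.warn(f"assembly {label!r} ({path}) yielded no usable k-mers")
    return AssemblyKmerSet(label=label, codes=codes, source_length=total, params=params)


def hamming_distance(x: AssemblyKmerSet, y: AssemblyKmerSet) -> int:
    """Size of the symmetric difference |Kx Δ Ky| = |Kx| + |Ky| - 2|Kx ∩ Ky|.

    Equals the Hamming distance between the two assembly bitmaps over the
    k-mer universe.
    """
    if x.params is not None and y.params is not None and x.params != y.params:
        raise ConfigurationError(
            f"k-mer sets {x.label!r} and {y.label!r} use different parameters"
        )
    inter = np.intersect1d(x.codes, y.codes, assume_unique=True)
    return len(x.codes) + len(y.codes) - 2 * len(inter)


def pairwise_distances(
    sets: Sequence[AssemblyKmerSet],
    distance_fn: Callable[[AssemblyKmerSet, AssemblyKmerSet], float] | None = None,
) -> DistanceMatrix:
    """Full symmetric distance matrix between assembly k-mer sets.

    ``distance_fn`` plugs in estimated distances (e.g. sketch-based)
    without changing downstream code; default is the exact symmetric
    difference.
    """
    if not sets:
        raise ConfigurationError("pairwise_distances requires at least one set")
    fn = distance_fn or hamming_distance
    n = len(sets)
    d = np.zeros((n, n), dtype=np.int64 if distance_fn is None else np.float64)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = fn(sets[i], sets[j])
            except ConfigurationError:
                raise
            except Exception as exc:
                raise RuntimeError(
                    f"distance function failed for pair "
                    f"({sets[i].label!r}, {sets[j].label!r}): {exc}"
                ) from exc
    return DistanceMatrix(n=n, d=d)


def nearest_neighbor_order(dist: DistanceMatrix, start_index: int = 0) -> ColumnOrder:
    """Greedy nearest-neighbor chain over the distance matrix.

    Starting from ``start_index``, repeatedly appends the unvisited column
    closest to the last appended one; ties break to the smallest column
    index (np.argmin returns the first minimum).  Deterministic given
    ``start_index``.
    """
    n = dist.n
    if not (0 <= start_index < n):
        raise ValueError(f"start_index {start_index} out of range for n={n}")
    visited = np.zeros(n, dtype=bool)
    order = [start_index]
    visited[start_index] = True
    for _ in range(n - 1):
        row = dist.d[order[-1]].astype(np.float64).copy()
        row[visited] = np.inf
        nxt = int(np.argmin(row))
        order.append(nxt)
        visited[nxt] = True
    return ColumnOrder(permutation=order, start_index=start_index)


def naive_runs_total(
    sets: Sequence[AssemblyKmerSet],
    order: ColumnOrder,
    universe_rows: int,
) -> int:
    """Total NRLE runs of the full presence matrix under a column order.

    Every row of the matrix contributes one baseline run (all-zero rows
    included) plus one run per bit change between consecutive ordered
    columns, so the total equals ``universe_rows`` plus the sum of Hamming
    distances along the ordered chain of columns.
    """
    distinct = len(np.unique(np.concatenate([s.codes for s in sets]))) if sets else 0
    if universe_rows < distinct:
        raise ConfigurationError(
            f"universe_rows={universe_rows} is smaller than the {distinct} "
            "distinct codes observed across the sets"
        )
    perm = order.permutation
    total = universe_rows
    for a, b in zip(perm, perm[1:]):
        total += hamming_distance(sets[a], sets[b])
    return total


def export_distances_tsv(
    dist: DistanceMatrix,
    labels: Sequence[str],
    order: ColumnOrder | None,
    path: str | Path,
) -> None:
    """Write the distance matrix (and chosen order) as a diagnostic TSV."""
    with open(path, "w") as fh:
        if order is not None:
            fh.write(
                "# column_order\t"
                + "\t".join(labels[i] for i in order.permutation)
                + "\n"
            )
        fh.write("label\t" + "\t".join(labels) + "\n")
        for i, lab in enumerate(labels):
            fh.write(lab + "\t" + "\t".join(str(int(v)) for v in dist.d[i]) + "\n")
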