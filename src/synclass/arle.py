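"""Naive and adaptive run-length encoding of bitmap rows.

A naive RLE (NRLE) stores a bitmap as maximal runs of identical bits.
The adaptive RLE (ARLE) additionally stores short stretches verbatim in
fixed-width *raw* words when encoding them as runs would cost more space.
With word width ``w``, one bit flags raw vs. compressed; compressed words
spend one more bit on the run's bit value, leaving ``w-2`` bits for the
run length (so a compressed run covers up to ``2**(w-2) - 1`` bits), while
raw words carry up to ``w-1`` literal bits.  The greedy left-to-right
encoder never uses more words than the NRLE uses runs.

Rows remain iterable over their set bits in time proportional to the word
count plus the number of set bits, which is what makes per-k-mer row
compression compatible with fast classification queries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np

from .errors import FormatError

__all__ = [
    "RunWord",
    "ARLERow",
    "nrle_encode",
    "nrle_run_count",
    "arle_encode",
    "arle_decode",
    "iter_set_bits",
    "adaptive_blocks_count",
    "row_to_words",
    "words_to_row",
]

ZEROS = "zeros"
ONES = "ones"
RAW = "raw"


class RunWord(NamedTuple):
    """One ARLE word: a zeros-run, a ones-run, or a raw literal block.

    ``length`` is the number of row bits the word covers; ``payload``
    holds the literal bits of a raw block, first covered bit in the most
    significant of the ``w-1`` payload positions.
    """

    kind: str
    length: int
    payload: int = 0


@dataclass
class ARLERow:
    """A compressed bitmap row: a word sequence plus the row bit length."""

    words: list[RunWord]
    row_length: int
    w: int = 16

    def word_count(self) -> int:
        return len(self.words)


def _as_bits(bitmap) -> np.ndarray:
    arr = np.asarray(bitmap, dtype=np.uint8)
    if arr.ndim != 1:
        raise ValueError("bitmap must be one-dimensional")
    return arr


def nrle_encode(bitmap) -> list[tuple[int, int]]:
    """Maximal (bit, length) runs of a bitmap; empty list for empty input."""
    bits = _as_bits(bitmap)
    if len(bits) == 0:
        return []
    change = np.flatnonzero(np.diff(bits)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(bits)]))
    return [(int(bits[s]), int(e - s)) for s, e in zip(starts, ends)]


def nrle_run_count(bitmap, max_run: int | None = None) -> int:
    """Number of NRLE runs, optionally splitting runs longer than
    ``max_run`` into separate runs.

    With word width ``w`` a run length field holds at most
    ``2**(w-2) - 1`` bits, so run counts comparable with ARLE word counts
    use ``max_run = 2**(w-2) - 1``; over-long runs count as multiple.
    """
    runs = nrle_encode(bitmap)
    if max_run is None:
        return len(runs)
    return sum(-(-length // max_run) for _, length in runs)


def arle_encode(bitmap, w: int = 16) -> ARLERow:
    """Greedy adaptive RLE of a bitmap with word width ``w`` (>= 4).

    Scans left to right: measure the current run, capped at
    ``2**(w-2) - 1`` bits.  A run shorter than ``w`` is folded into a raw
    word covering the next ``min(w-1, remaining)`` bits verbatim;
    otherwise one compressed word covers the run.
    """
    if w < 4:
        raise ValueError(f"word width must be >= 4, got {w}")
    bits = _as_bits(bitmap)
    n = len(bits)
    cap = (1 << (w - 2)) - 1
    words: list[RunWord] = []
    i = 0
    while i < n:
        b = bits[i]
        j = i + 1
        while j < n and bits[j] == b and (j - i) < cap:
            j += 1
        run = j - i
        if run < w:
            length = min(w - 1, n - i)
            payload = 0
            for q in range(length):
                payload |= int(bits[i + q]) << (w - 2 - q)
            words.append(RunWord(RAW, length, payload))
            i += length
        else:
            words.append(RunWord(ONES if b else ZEROS, run))
            i = j
    return ARLERow(words=words, row_length=n, w=w)


def arle_decode(row: ARLERow) -> np.ndarray:
    """Reconstruct the exact bitmap; inverse of :func:`arle_encode`."""
    out = np.empty(row.row_length, dtype=np.uint8)
    pos = 0
    for word in row.words:
        if pos + word.length > row.row_length:
            raise FormatError(
                f"ARLE words cover {pos + word.length} bits but row length "
                f"is {row.row_length}"
            )
        if word.kind == ZEROS:
            out[pos : pos + word.length] = 0
        elif word.kind == ONES:
            out[pos : pos + word.length] = 1
        elif word.kind == RAW:
            for q in range(word.length):
                out[pos + q] = (word.payload >> (row.w - 2 - q)) & 1
        else:
            raise FormatError(f"unknown word kind {word.kind!r}")
        pos += word.length
    if pos != row.row_length:
        raise FormatError(
            f"ARLE words cover {pos} bits but row length is {row.row_length}"
        )
    return out


def iter_set_bits(row: ARLERow) -> Iterator[int]:
    """Yield set-bit column indices in ascending order.

    Work is proportional to the word count plus the number of set bits:
    zero runs are skipped in O(1) and raw payloads are scanned bit by bit
    only within their (at most w-1) covered positions.
    """
    pos = 0
    for word in row.words:
        if word.kind == ONES:
            yield from range(pos, pos + word.length)
        elif word.kind == RAW:
            payload = word.payload
            for q in range(word.length):
                if (payload >> (row.w - 2 - q)) & 1:
                    yield pos + q
        pos += word.length


def adaptive_blocks_count(bitmaps: Iterable, w: int = 16) -> int:
    """Total ARLE word count over a collection of rows.

    By construction this never exceeds the total NRLE run count of the
    same rows.
    """
    return sum(arle_encode(b, w).word_count() for b in bitmaps)


# ---------------------------------------------------------------------------
# word-level packing (serialization layout)
#
# bit w-1 (MSB) = 1 for compressed, 0 for raw
# compressed: bit w-2 = run bit value, low w-2 bits = run length
# raw: low w-1 bits = payload, first covered column in the highest payload bit
# A trailing partial raw block is disambiguated by the decoder tracking the
# remaining row length; raw words carry no explicit length field.


def row_to_words(row: ARLERow) -> list[int]:
    """Pack a row into ``w``-bit unsigned integers for serialization."""
    w = row.w
    out = []
    for word in row.words:
        if word.kind == RAW:
            out.append(word.payload & ((1 << (w - 1)) - 1))
        else:
            value = 1 << (w - 1)
            if word.kind == ONES:
                value |= 1 << (w - 2)
            value |= word.length
            out.append(value)
    return out


def words_to_row(words: Sequence[int], w: int, row_length: int) -> ARLERow:
    """Unpack ``w``-bit integers into an :class:`ARLERow`.

    Raises :class:`FormatError` when the words do not cover exactly
    ``row_length`` bits.
    """
    decoded: list[RunWord] = []
    pos = 0
    for value in words:
        if pos >= row_length and words:
            raise FormatError("ARLE word stream longer than row length")
        if value >> (w - 1):
            kind = ONES if (value >> (w - 2)) & 1 else ZEROS
            length = value & ((1 << (w - 2)) - 1)
            if length == 0:
                raise FormatError("compressed ARLE word with zero length")
            decoded.append(RunWord(kind, length))
        else:
            length = min(w - 1, row_length - pos)
            decoded.append(RunWord(RAW, length, value))
        pos += decoded[-1].length
    if pos != row_length:
        raise FormatError(
            f"ARLE word stream covers {pos} bits, expected {row_length}"
        )
    return ARLERow(words=decoded, row_length=row_length, w=w)
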