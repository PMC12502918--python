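"""Integer k-mer encoding, canonicalization and open-syncmer extraction.

A k-mer over the DNA alphabet is packed into an unsigned integer by
assigning 2 bits per base (A=0, C=1, G=2, T=3) with the first base in the
most significant position, so integer order coincides with lexicographic
order.  The *canonical* form of a k-mer is the smaller of the k-mer and its
reverse complement under that order.

An *open syncmer* is a k-mer whose minimal s-mer (substring of length
``s < k``, ties broken by leftmost occurrence) starts exactly at offset
``t``.  Open syncmers give a position-independent ~1/(k-s+1) subsample of
the k-mers of a sequence that is robust to single-base errors, which makes
them a good fit for indexing noisy long reads.  The default parameters are
k=15, s=9, t=2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import InvalidBaseError

__all__ = [
    "SyncmerParams",
    "KmerUniverse",
    "encode_kmer",
    "decode_kmer",
    "revcomp_code",
    "canonical_code",
    "is_open_syncmer",
    "extract_kmers",
    "universe_size",
    "syncmer_density",
]

_BASES = "ACGT"

# 256-entry lookup: byte value of a base character -> 2-bit code, -1 otherwise
_BASE_VALS = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _BASE_VALS[ord(_b)] = _i
    _BASE_VALS[ord(_b.lower())] = _i

# Exact universe enumeration is refused above this k (4^12 ≈ 1.7e7 codes).
EXACT_ENUMERATION_LIMIT = 12


@dataclass(frozen=True)
class SyncmerParams:
    """Parameters controlling k-mer extraction and subsampling.

    Attributes
    ----------
    k : int
        k-mer length in bases, 1 <= k <= 31 (codes fit one 64-bit word).
    s : int
        s-mer length for the syncmer test, s < k.
    t : int
        Required 0-indexed start of the minimal s-mer, 0 <= t <= k - s.
    subsample_mode : str
        ``"syncmer"`` keeps only open syncmers, ``"none"`` keeps every
        window.
    canonicalize : bool
        Collapse each k-mer with its reverse complement.
    """

    k: int = 15
    s: int = 9
    t: int = 2
    subsample_mode: str = "syncmer"
    canonicalize: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.k <= 31):
            raise ValueError(f"k must be in [1, 31], got {self.k}")
        if self.subsample_mode not in ("syncmer", "none"):
            raise ValueError(f"unknown subsample_mode {self.subsample_mode!r}")
        if self.subsample_mode == "syncmer":
            if not (1 <= self.s < self.k):
                raise ValueError(f"require 1 <= s < k, got s={self.s}, k={self.k}")
            if not (0 <= self.t <= self.k - self.s):
                raise ValueError(f"require 0 <= t <= k-s, got t={self.t}")


@dataclass(frozen=True)
class KmerUniverse:
    """Size of the k-mer universe U under the given extraction rules."""

    params: SyncmerParams
    size: float
    method: str  # "exact" or "montecarlo"
    samples: int = 0


def encode_kmer(seq: str) -> int:
    """Pack a k-mer string into its integer code (A=0, C=1, G=2, T=3)."""
    code = 0
    for pos, ch in enumerate(seq):
        v = _BASE_VALS[ord(ch)] if ord(ch) < 256 else -1
        if v < 0:
            raise InvalidBaseError(
                f"invalid base {ch!r} at position {pos} in k-mer {seq!r}"
            )
        code = (code << 2) | int(v)
    return code


def decode_kmer(code: int, k: int) -> str:
    """Inverse of :func:`encode_kmer`."""
    if not (0 <= code < 4**k):
        raise ValueError(f"code {code} out of range for k={k}")
    return "".join(_BASES[(code >> (2 * (k - 1 - i))) & 3] for i in range(k))


def revcomp_code(code: int, k: int) -> int:
    """Code of the reverse complement of the k-mer with the given code."""
    if not (0 <= code < 4**k):
        raise ValueError(f"code {code} out of range for k={k}")
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | (3 - (code & 3))
        code >>= 2
    return rc


def canonical_code(code: int, k: int) -> int:
    """Lexicographic minimum of a k-mer code and its reverse complement."""
    return min(code, revcomp_code(code, k))


def is_open_syncmer(code: int, params: SyncmerParams) -> bool:
    """True iff the minimal s-mer of the k-mer first occurs at offset t."""
    k, s, t = params.k, params.s, params.t
    if not (0 <= code < 4**k):
        raise ValueError(f"code {code} out of range for k={k}")
    smask = (1 << (2 * s)) - 1
    # s-mer starting at offset q occupies bits [2*(k-s-q), 2*(k-q))
    best, best_pos = None, -1
    for q in range(k - s + 1):
        sm = (code >> (2 * (k - s - q))) & smask
        if best is None or sm < best:
            best, best_pos = sm, q
    return best_pos == t


# ---------------------------------------------------------------------------
# vectorized internals


def _seq_to_vals(sequence: str) -> np.ndarray:
    """Map a DNA string to int8 2-bit values; non-ACGT becomes -1."""
    raw = np.frombuffer(sequence.encode("latin-1", errors="replace"), dtype=np.uint8)
    return _BASE_VALS[raw]


def _pack(vals: np.ndarray) -> np.ndarray:
    """Pack an (N, k) matrix of 2-bit values into N integer codes."""
    k = vals.shape[1]
    pw = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return vals.astype(np.int64) @ pw


def _unpack(codes: np.ndarray, k: int) -> np.ndarray:
    """Expand N integer codes into an (N, k) matrix of 2-bit values."""
    shifts = 2 * np.arange(k - 1, -1, -1, dtype=np.int64)
    return ((codes[:, None] >> shifts) & 3).astype(np.int8)


def _syncmer_mask(vals: np.ndarray, s: int, t: int) -> np.ndarray:
    """Row-wise open-syncmer test on an (N, k) matrix of base values.

    ``argmin`` returns the first occurrence, which implements the
    leftmost tie-break of the minimal s-mer.
    """
    windows = sliding_window_view(vals, s, axis=1)  # (N, k-s+1, s)
    pw = 4 ** np.arange(s - 1, -1, -1, dtype=np.int64)
    scodes = windows.astype(np.int64) @ pw
    return scodes.argmin(axis=1) == t


def _rc_codes(vals: np.ndarray) -> np.ndarray:
    """Reverse-complement codes for an (N, k) matrix of base values."""
    return _pack(3 - vals[:, ::-1])


def _apply_rules(
    vals: np.ndarray, params: SyncmerParams, canonical_before_syncmer: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Canonicalize and subsample packed windows.

    Parameters
    ----------
    vals : (N, k) int8 matrix of valid windows (values 0..3).
    canonical_before_syncmer : bool
        When True (default pipeline) the syncmer test is applied to the
        canonical form of each window; when False it is applied to the
        window as read, and the surviving windows are canonicalized
        afterwards.

    Returns
    -------
    codes : emitted codes for every input window (before masking)
    keep : boolean mask of windows that pass the subsampling rule
    """
    fwd = _pack(vals)
    if params.canonicalize:
        rc = _rc_codes(vals)
        codes = np.minimum(fwd, rc)
    else:
        codes = fwd

    if params.subsample_mode == "none":
        return codes, np.ones(len(codes), dtype=bool)

    if params.canonicalize and canonical_before_syncmer:
        keep = _syncmer_mask(_unpack(codes, params.k), params.s, params.t)
    else:
        keep = _syncmer_mask(vals, params.s, params.t)
    return codes, keep


def extract_kmers(
    sequence: str,
    params: SyncmerParams,
    *,
    canonical_before_syncmer: bool = True,
) -> np.ndarray:
    """Extract k-mer codes from a DNA sequence.

    Slides a k-base window over the sequence.  Windows containing any
    non-ACGT character are skipped.  Each surviving window is
    canonicalized when ``params.canonicalize`` and, in syncmer mode,
    emitted only if it passes the open-syncmer test (applied to the
    canonical form by default).  Output preserves window order and
    multiplicity; callers deduplicate for reference sets.

    Returns an int64 array of codes (empty for sequences shorter than k).
    """
    k = params.k
    vals = _seq_to_vals(sequence)
    if len(vals) < k:
        return np.empty(0, dtype=np.int64)
    windows = sliding_window_view(vals, k)
    valid = (windows >= 0).all(axis=1)
    wv = np.ascontiguousarray(windows[valid])
    if len(wv) == 0:
        return np.empty(0, dtype=np.int64)
    codes, keep = _apply_rules(wv, params, canonical_before_syncmer)
    return codes[keep]


def _membership_mask(
    codes: np.ndarray, params: SyncmerParams, canonical_before_syncmer: bool
) -> np.ndarray:
    """True where a code belongs to the universe U (canonical fixed point
    that passes the subsampling rule)."""
    mask = np.ones(len(codes), dtype=bool)
    vals = _unpack(codes, params.k)
    if params.canonicalize:
        mask &= _rc_codes(vals) >= codes
    if params.subsample_mode == "syncmer":
        # For members, the code is its own canonical form, so the test
        # target is the same either way; the switch matters only for
        # which windows of a read are emitted.
        mask &= _syncmer_mask(vals, params.s, params.t)
    return mask


_universe_cache: dict[tuple, KmerUniverse] = {}


def universe_size(
    params: SyncmerParams,
    method: str = "exact",
    samples: int = 10**6,
    seed: int = 1,
    *,
    chunk: int = 1 << 20,
) -> KmerUniverse:
    """Count (or estimate) the number of k-mer codes in the universe U.

    ``exact`` enumerates all 4**k codes and is refused for
    k > ``EXACT_ENUMERATION_LIMIT``; ``montecarlo`` draws ``samples``
    uniform codes (>= 1e5) and returns the unbiased estimate
    4**k * (fraction in U), deterministic for a fixed seed.  Results are
    cached per argument tuple.
    """
    key = (params, method, samples if method == "montecarlo" else 0,
           seed if method == "montecarlo" else 0)
    if key in _universe_cache:
        return _universe_cache[key]

    total = 4**params.k
    if method == "exact":
        if params.k > EXACT_ENUMERATION_LIMIT:
            raise ValueError(
                f"exact universe enumeration refused for k={params.k} > "
                f"{EXACT_ENUMERATION_LIMIT}; use method='montecarlo'"
            )
        count = 0
        for lo in range(0, total, chunk):
            codes = np.arange(lo, min(lo + chunk, total), dtype=np.int64)
            count += int(_membership_mask(codes, params, True).sum())
        result = KmerUniverse(params, float(count), "exact")
    elif method == "montecarlo":
        if samples < 10**5:
            raise ValueError("montecarlo requires samples >= 1e5")
        rng = np.random.default_rng(seed)
        hits = 0
        remaining = samples
        while remaining > 0:
            m = min(chunk, remaining)
            codes = rng.integers(0, total, size=m, dtype=np.int64)
            hits += int(_membership_mask(codes, params, True).sum())
            remaining -= m
        result = KmerUniverse(params, total * hits / samples, "montecarlo", samples)
    else:
        raise ValueError(f"unknown method {method!r}")

    _universe_cache[key] = result
    return result


def syncmer_density(
    params: SyncmerParams,
    samples: int = 10**6,
    seed: int = 1,
    *,
    canonical_before_syncmer: bool = True,
    chunk: int = 1 << 20,
) -> float:
    """Fraction of uniform random k-mers emitted by the extraction rules.

    This is the per-window emission probability (the expected number of
    queries a read of length L contributes is ~ density * (L - k + 1)),
    distinct from |U| / 4**k, which counts distinct canonical codes.
    """
    rng = np.random.default_rng(seed)
    total = 4**params.k
    hits = 0
    remaining = samples
    while remaining > 0:
        m = min(chunk, remaining)
        codes = rng.integers(0, total, size=m, dtype=np.int64)
        vals = _unpack(codes, params.k)
        _, keep = _apply_rules(vals, params, canonical_before_syncmer)
        hits += int(keep.sum())
        remaining -= m
    return hits / samples
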