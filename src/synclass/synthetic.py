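"""Seeded mock communities and error-bearing reads with ground truth.

Stands in for real nanopore runs when building and testing classifiers:
genomes are uniform i.i.d. sequence (optionally derived from a common
ancestor at a given per-base divergence, which produces the shared-k-mer
structure of closely related strains), and reads carry independent
per-base substitutions, insertions and deletions at configurable rates.
Reverse-strand reads are emitted reverse-complemented, exercising
canonicalization end to end.  A configurable fraction of reads is drawn
from a withheld genome and labeled ``OUT_OF_DB`` so the false-positive
behavior of a classifier on novel sequence can be measured.

All outputs are byte-deterministic for a given seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .evaluation import OUT_OF_DB

__all__ = [
    "ErrorModel",
    "ReadTruth",
    "SimulatedRead",
    "random_genome",
    "mock_community",
    "write_community_fastas",
    "simulate_reads",
    "truncate_reads",
    "write_fastq",
    "write_truth_tsv",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class ErrorModel:
    """Independent per-base error rates (each in [0, 1), sum < 1)."""

    substitution: float = 0.0
    insertion: float = 0.0
    deletion: float = 0.0

    def __post_init__(self) -> None:
        rates = (self.substitution, self.insertion, self.deletion)
        if any(r < 0 or r >= 1 for r in rates) or sum(rates) >= 1:
            raise ValueError(f"invalid error rates {rates}")

    @property
    def total(self) -> float:
        return self.substitution + self.insertion + self.deletion


@dataclass
class ReadTruth:
    read_id: str
    label: str  # source assembly label or OUT_OF_DB
    position: int
    strand: str  # "+" or "-"


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str


def random_genome(length: int, seed: int) -> str:
    """Uniform i.i.d. ACGT sequence, deterministic per seed."""
    if length < 0:
        raise ValueError("length must be >= 0")
    rng = np.random.default_rng(seed)
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _mutate(sequence: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    # substitute with one of the three other bases
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def mock_community(
    n_genomes: int,
    genome_length: int,
    divergence: float | None = None,
    seed: int = 0,
) -> dict[str, str]:
    """Generate labeled genomes ``g000``, ``g001``, ...

    With ``divergence`` unset the genomes are independent (negligible
    k-mer sharing for k >= 15); otherwise one ancestor is generated and
    each genome is a copy mutated at the given per-base substitution rate
    (near-identical strains with heavily shared k-mer sets).
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    rng = np.random.default_rng(seed)
    community: dict[str, str] = {}
    if divergence is None:
        for i in range(n_genomes):
            seq = _BASES[rng.integers(0, 4, size=genome_length)].tobytes()
            community[f"g{i:03d}"] = seq.decode("ascii")
    else:
        ancestor = _BASES[rng.integers(0, 4, size=genome_length)].tobytes().decode()
        for i in range(n_genomes):
            community[f"g{i:03d}"] = _mutate(ancestor, divergence, rng)
    return community


def write_community_fastas(
    community: Mapping[str, str], outdir: str | Path, width: int = 80
) -> list[Path]:
    """Write one FASTA file per genome; returns the paths (label order)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for label, seq in community.items():
        path = outdir / f"{label}.fasta"
        with open(path, "w") as fh:
            fh.write(f">{label}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
        paths.append(path)
    return paths


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _apply_errors(seq: str, model: ErrorModel, rng: np.random.Generator) -> str:
    if model.total == 0:
        return seq
    out = []
    for ch in seq:
        r = rng.random()
        if r < model.deletion:
            continue
        if r < model.deletion + model.insertion:
            out.append(chr(_BASES[rng.integers(0, 4)]))
            out.append(ch)
        elif r < model.deletion + model.insertion + model.substitution:
            others = [b for b in "ACGT" if b != ch]
            out.append(others[rng.integers(0, 3)])
        else:
            out.append(ch)
    return "".join(out)


def simulate_reads(
    community: Mapping[str, str],
    n_reads: int,
    length_distribution: int | tuple[str, float, float],
    error_model: ErrorModel = ErrorModel(),
    out_of_db_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[list[SimulatedRead], list[ReadTruth]]:
    """Draw reads from random genomes, positions and strands.

    ``length_distribution`` is either a fixed length or
    ``("lognormal", mean_log, sigma_log)``.  Exactly
    ``floor(out_of_db_fraction * n_reads)`` reads come from a withheld
    random genome (as long as the longest community genome) and carry the
    ``OUT_OF_DB`` truth label.  Reads longer than their source genome are
    truncated to the maximum possible length with a warning.
    """
    if not community:
        raise ValueError("community must be non-empty")
    if not (0 <= out_of_db_fraction <= 1):
        raise ValueError("out_of_db_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = list(community)
    max_len = max(len(s) for s in community.values())
    withheld = (
        _BASES[rng.integers(0, 4, size=max_len)].tobytes().decode("ascii")
        if out_of_db_fraction > 0
        else ""
    )
    n_out = int(out_of_db_fraction * n_reads)
    is_out = np.zeros(n_reads, dtype=bool)
    if n_out:
        is_out[rng.permutation(n_reads)[:n_out]] = True

    reads: list[SimulatedRead] = []
    truth: list[ReadTruth] = []
    warned = False
    for i in range(n_reads):
        if is_out[i]:
            label, genome = OUT_OF_DB, withheld
        else:
            label = labels[rng.integers(0, len(labels))]
            genome = community[label]
        if isinstance(length_distribution, int):
            length = length_distribution
        else:
            kind, mu, sigma = length_distribution
            if kind != "lognormal":
                raise ValueError(f"unknown length distribution {kind!r}")
            length = max(1, int(rng.lognormal(mu, sigma)))
        if length > len(genome):
            if not warned:
                warnings.warn(
                    "requested read length exceeds genome length; truncating"
                )
                warned = True
            length = len(genome)
        pos = int(rng.integers(0, len(genome) - length + 1))
        fragment = genome[pos : pos + length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            fragment = _revcomp(fragment)
        fragment = _apply_errors(fragment, error_model, rng)
        read_id = f"read{i:06d}"
        reads.append(SimulatedRead(read_id, fragment))
        truth.append(ReadTruth(read_id, label, pos, strand))
    return reads, truth


def truncate_reads(
    reads: Sequence[SimulatedRead], max_length: int
) -> list[SimulatedRead]:
    """Keep only the first ``max_length`` bases of each read (ids kept).

    Emulates the prefix an adaptive-sampling controller can inspect before
    deciding whether to eject the molecule; shorter reads pass unchanged.
    """
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    return [
        SimulatedRead(r.read_id, r.sequence[:max_length]) for r in reads
    ]


def write_fastq(reads: Sequence[SimulatedRead], path: str | Path) -> None:
    """Write reads as FASTQ with dummy quality scores."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def write_truth_tsv(truth: Sequence[ReadTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tlabel\tposition\tstrand\n")
        for t in truth:
            fh.write(f"{t.read_id}\t{t.label}\t{t.position}\t{t.strand}\n")
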