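import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from synclass import AssemblyKmerSet, SyncmerParams, extract_kmers

# The six-assembly, k=2 worked example used throughout the tests.
EXAMPLE_ASSEMBLIES = {
    "a1": "AATCTAA",
    "a2": "TAGACAT",
    "a3": "GGACGCT",
    "a4": "CATAACT",
    "a5": "CTCTAGA",
    "a6": "CCGCTGG",
}

K2_ALL = SyncmerParams(k=2, subsample_mode="none", canonicalize=False)


def kmer_set(label: str, sequence: str, params: SyncmerParams) -> AssemblyKmerSet:
    codes = np.unique(extract_kmers(sequence, params))
    return AssemblyKmerSet(label, codes, len(sequence), params)


@pytest.fixture(scope="session")
def example_sets() -> list[AssemblyKmerSet]:
    return [kmer_set(l, s, K2_ALL) for l, s in EXAMPLE_ASSEMBLIES.items()]


@pytest.fixture(scope="session")
def k2_params() -> SyncmerParams:
    return K2_ALL


def brute_force_kmer_set(sequence: str, k: int) -> set[str]:
    """String-level oracle: distinct k-length windows over ACGT only."""
    return {
        sequence[i : i + k]
        for i in range(len(sequence) - k + 1)
        if set(sequence[i : i + k]) <= set("ACGT")
    }


def write_fasta(path, label, sequence, width=60):
    with open(path, "w") as fh:
        fh.write(f">{label}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i : i + width] + "\n")
    return path
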