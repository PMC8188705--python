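"""Small sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: byte values of the four nucleotides, used when sampling random sequence
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random A/C/G/T string of the given length."""
    if length < 0:
        raise ValueError("length must be non-negative")
    idx = rng.integers(0, 4, size=length)
    return _BASES[idx].tobytes().decode("ascii")


def normalize(seq: str) -> str:
    """Uppercase and collapse anything outside A/C/G/T to N."""
    seq = seq.upper()
    if all(c in "ACGTN" for c in seq):
        return seq
    return "".join(c if c in "ACGTN" else "N" for c in seq)


def kmer_set(seq: str, k: int, circular: bool = False) -> set[str]:
    """All k-mers of *seq*; includes origin-wrapping k-mers when circular."""
    s = seq + seq[: k - 1] if circular and len(seq) >= k else seq
    return {s[i : i + k] for i in range(len(s) - k + 1)}
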