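"""Small nucleotide-sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_DNA_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_RNA_COMPLEMENT = str.maketrans("ACGUNacgun", "UGCANugcan")

# byte-level complement table for vectorised context calling
COMPLEMENT_BYTES = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    COMPLEMENT_BYTES[_a] = _b


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def revcomp_rna(seq: str) -> str:
    """Reverse complement of an RNA string."""
    return seq.translate(_RNA_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    """Normalize a DNA/RNA string to upper-case RNA alphabet."""
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def random_seq(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    letters = np.array(list(alphabet))
    return "".join(letters[rng.integers(0, len(letters), size=length)])
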