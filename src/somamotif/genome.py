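"""Reference sequences, IUPAC degeneracy and strand arithmetic.

All sequences are upper-case ACGT strings internally; positions exposed to
callers are 1-based (VCF convention) while slicing helpers use 0-based
half-open coordinates (BED convention).
"""
from __future__ import annotations

import os
from typing import Dict, Iterator, Mapping

import numpy as np

BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_COMP_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: full IUPAC degeneracy map (lower-case codes as used in motif patterns)
IUPAC: Dict[str, frozenset] = {
    "a": frozenset("A"),
    "c": frozenset("C"),
    "g": frozenset("G"),
    "t": frozenset("T"),
    "r": frozenset("AG"),
    "y": frozenset("CT"),
    "s": frozenset("CG"),
    "w": frozenset("AT"),
    "k": frozenset("GT"),
    "m": frozenset("AC"),
    "b": frozenset("CGT"),
    "d": frozenset("AGT"),
    "h": frozenset("ACT"),
    "v": frozenset("ACG"),
    "n": frozenset("ACGT"),
}

#: IUPAC code whose base set is the complement of each code's set
IUPAC_COMPLEMENT = {
    "a": "t", "c": "g", "g": "c", "t": "a",
    "r": "y", "y": "r", "s": "s", "w": "w", "k": "m", "m": "k",
    "b": "v", "d": "h", "h": "d", "v": "b", "n": "n",
}

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def complement(base: str) -> str:
    return _COMP[base.upper()]


def revcomp(seq: str) -> str:
    """Reverse complement of a plain-nucleotide string."""
    return seq.translate(_COMP_TABLE)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 (A=0, C=1, G=2, T=3; other=255)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class Reference(Mapping):
    """A mapping of contig name to sequence with cached integer encoding.

    Construct from a dict of strings or from a FASTA file via
    :meth:`from_fasta`.  ``fetch(chrom, start0, end0)`` returns the 0-based
    half-open slice; ``base_at(chrom, pos1)`` the single 1-based base.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: str(seq).upper() for name, seq in sequences.items()}
        self._encoded: Dict[str, np.ndarray] = {}

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "Reference":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def to_fasta(self, path: str | os.PathLike, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def length(self, name: str) -> int:
        return len(self._seqs[name])

    def fetch(self, chrom: str, start0: int, end0: int) -> str:
        return self._seqs[chrom][max(start0, 0) : end0]

    def base_at(self, chrom: str, pos1: int) -> str:
        return self._seqs[chrom][pos1 - 1]

    def trinucleotide(self, chrom: str, pos1: int) -> str | None:
        """±1 context around a 1-based position, or None at contig edges."""
        seq = self._seqs[chrom]
        if pos1 < 2 or pos1 > len(seq) - 1:
            return None
        return seq[pos1 - 2 : pos1 + 1]

    def encoded(self, chrom: str) -> np.ndarray:
        arr = self._encoded.get(chrom)
        if arr is None:
            arr = encode(self._seqs[chrom])
            self._encoded[chrom] = arr
        return arr

    def reverse_complemented(self) -> "Reference":
        """A new Reference with every contig reverse-complemented."""
        return Reference({name: revcomp(seq) for name, seq in self._seqs.items()})
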