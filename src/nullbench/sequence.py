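"""Strict-alphabet DNA sequences and their base-composition bookkeeping.

All models in this package are defined over the four-letter alphabet
``{A, C, G, T}``.  Ambiguity codes are rejected outright: a probability
model over ACGT assigns no meaningful likelihood to an ``N``, so silently
accepting one would corrupt every downstream score.

Internally sequences are encoded as ``uint8`` codes (A=0, C=1, G=2, T=3)
so that large stratified datasets can be scored with vectorised numpy
arithmetic on code matrices rather than per-character Python loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"
A, C, G, T = 0, 1, 2, 3
GC_CODES = (C, G)

# byte value -> code, 255 for anything outside ACGT
_BYTE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET.encode()):
    _BYTE_TO_CODE[_b] = _i
_CODE_TO_BYTE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)


class AlphabetError(ValueError):
    """A residue outside {A, C, G, T} was encountered."""


def encode(residues: str, *, name: str = "<sequence>") -> np.ndarray:
    """Encode an ACGT string as a ``uint8`` code array.

    Raises :class:`AlphabetError` naming the offending record if any
    residue falls outside the strict alphabet.
    """
    raw = np.frombuffer(residues.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _BYTE_TO_CODE[raw]
    bad = codes == 255
    if bad.any():
        pos = int(np.argmax(bad))
        raise AlphabetError(
            f"record {name!r}: invalid residue {residues[pos]!r} at position "
            f"{pos + 1} (only A, C, G, T are accepted)"
        )
    return codes


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _CODE_TO_BYTE[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def gc_mark(gc_count: int, length: int) -> int:
    """Integer GC percentage mark: round(100*gc_count/length).

    Rounding is half-away-from-zero, computed in exact integer
    arithmetic to avoid float-tie artefacts (counts are non-negative, so
    this is ``floor(100*gc/L + 1/2)``).
    """
    return (200 * gc_count + length) // (2 * length)


@dataclass(frozen=True)
class NucleotideSequence:
    """A named DNA sequence over the strict ACGT alphabet.

    Parameters
    ----------
    id
        Record label, carried through FASTA round trips and score tables.
    residues
        The sequence string; validated on construction.
    """

    id: str
    residues: str
    _codes: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        object.__setattr__(self, "_codes", encode(self.residues, name=self.id))

    @classmethod
    def from_codes(cls, id: str, codes: np.ndarray) -> "NucleotideSequence":
        return cls(id=id, residues=decode(codes))

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def codes(self) -> np.ndarray:
        return self._codes

    @property
    def counts(self) -> np.ndarray:
        """Base counts ``(c_A, c_C, c_G, c_T)``; sums to the length."""
        return np.bincount(self._codes, minlength=4).astype(np.int64)

    @property
    def gc_count(self) -> int:
        c = self.counts
        return int(c[C] + c[G])

    @property
    def gc_fraction(self) -> float:
        return self.gc_count / len(self)

    @property
    def mark(self) -> int:
        """Integer GC percentage mark of this sequence."""
        return gc_mark(self.gc_count, len(self))


def counts_matrix(codes: np.ndarray) -> np.ndarray:
    """Per-row base counts of a 2-D code matrix, shape ``(n, 4)``."""
    codes = np.asarray(codes)
    n, L = codes.shape
    out = np.empty((n, 4), dtype=np.int64)
    for b in range(4):
        out[:, b] = np.count_nonzero(codes == b, axis=1)
    return out
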