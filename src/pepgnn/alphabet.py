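"""Mixed L/D amino-acid alphabet, peptide sequences and sequence-space accounting.

Sequences are written in a one-letter dialect where uppercase letters denote
L-amino acids and lowercase letters denote their D-stereoisomers
(``YFPGQFAFS`` is all-L chemerin-9; ``yLPsQYAFf`` carries D-Tyr, D-Ser and
D-Phe).  Every distinct (letter, chirality) pair is a separate residue *type*
with its own integer index; those indices key the weight tables of the
network models, so the alphabet is the single source of truth for model
dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .errors import InvalidInputError, UnknownResidueError

# The 20 proteinogenic L-amino acids, alphabetical one-letter codes.
L_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

# Default D-residue subset: the 15 chiral residues whose D-forms ship in the
# default alphabet (glycine is achiral and C/D/G/I/M are omitted to keep the
# total at 35 types).  User-defined alphabets may choose any subset.
DEFAULT_D_LETTERS = "AEFHKLNPQRSTVWY"


@dataclass(frozen=True)
class Residue:
    """A residue *type*: one-letter code plus chirality.

    ``type_index`` is the row of this type in any weight table built over the
    governing alphabet.  D- and L-forms of the same letter are distinct types.
    """

    letter: str  # canonical uppercase one-letter code
    chirality: str  # "L" or "D"
    type_index: int

    def __post_init__(self):
        if len(self.letter) != 1 or not self.letter.isalpha():
            raise InvalidInputError(f"residue letter must be a single letter, got {self.letter!r}")
        if self.chirality not in ("L", "D"):
            raise InvalidInputError(f"chirality must be 'L' or 'D', got {self.chirality!r}")
        object.__setattr__(self, "letter", self.letter.upper())

    @property
    def char(self) -> str:
        """Display character: uppercase for L, lowercase for D."""
        return self.letter if self.chirality == "L" else self.letter.lower()


class Alphabet:
    """Ordered collection of residue types; size ``M`` fixes model width."""

    def __init__(self, residues: Iterable[Residue]):
        self.residues: tuple[Residue, ...] = tuple(residues)
        seen: dict[str, Residue] = {}
        for i, r in enumerate(self.residues):
            if r.type_index != i:
                raise InvalidInputError(
                    f"residue {r.char!r} has type_index {r.type_index}, expected {i}"
                )
            if r.char in seen:
                raise InvalidInputError(f"duplicate residue {r.char!r} in alphabet")
            seen[r.char] = r
        self._by_char = seen

    @property
    def size(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Alphabet):
            return NotImplemented
        return [(r.letter, r.chirality) for r in self.residues] == [
            (r.letter, r.chirality) for r in other.residues
        ]

    def __contains__(self, char: str) -> bool:
        return char in self._by_char

    def lookup(self, char: str) -> Residue:
        try:
            return self._by_char[char]
        except KeyError:
            raise UnknownResidueError(char, 1) from None

    def chars(self) -> str:
        return "".join(r.char for r in self.residues)

    # -- serialization ---------------------------------------------------

    def to_pairs(self) -> list[list[str]]:
        return [[r.letter, r.chirality] for r in self.residues]

    @classmethod
    def from_pairs(cls, pairs: Iterable[Iterable[str]]) -> "Alphabet":
        return cls(
            Residue(letter, chirality, i)
            for i, (letter, chirality) in enumerate(pairs)
        )

    def write(self, path: str | Path) -> None:
        """Write one ``letter,chirality`` line per residue."""
        Path(path).write_text(
            "".join(f"{r.letter},{r.chirality}\n" for r in self.residues)
        )

    @classmethod
    def read(cls, path: str | Path) -> "Alphabet":
        pairs = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 2:
                raise InvalidInputError(
                    f"{path}:{lineno}: expected 'letter,chirality', got {line!r}"
                )
            pairs.append(parts)
        return cls.from_pairs(pairs)


def default_alphabet() -> Alphabet:
    """The 35-letter alphabet: 20 L-residues plus 15 D-residues."""
    residues = []
    for letter in L_LETTERS:
        residues.append(Residue(letter, "L", len(residues)))
    for letter in DEFAULT_D_LETTERS:
        residues.append(Residue(letter, "D", len(residues)))
    return Alphabet(residues)


class Peptide:
    """An ordered residue sequence over one alphabet.

    Internally stored as an integer vector of residue type indices, which is
    the representation the network and the genetic algorithm operate on.
    """

    __slots__ = ("alphabet", "type_indices")

    def __init__(self, alphabet: Alphabet, type_indices: np.ndarray):
        idx = np.asarray(type_indices, dtype=np.intp)
        if idx.ndim != 1 or idx.size == 0:
            raise InvalidInputError("peptide must contain at least one residue")
        if idx.min() < 0 or idx.max() >= alphabet.size:
            raise InvalidInputError("type index outside alphabet")
        self.alphabet = alphabet
        self.type_indices = idx
        self.type_indices.setflags(write=False)

    @property
    def residues(self) -> tuple[Residue, ...]:
        return tuple(self.alphabet.residues[i] for i in self.type_indices)

    def __len__(self) -> int:
        return int(self.type_indices.size)

    def __str__(self) -> str:
        return decode_peptide(self)

    def __repr__(self) -> str:
        return f"Peptide({decode_peptide(self)!r})"

    def __eq__(self, other) -> bool:
        if not isinstance(other, Peptide):
            return NotImplemented
        return (
            self.alphabet == other.alphabet
            and np.array_equal(self.type_indices, other.type_indices)
        )

    def __hash__(self) -> int:
        return hash((self.alphabet.chars(), self.type_indices.tobytes()))


def encode_peptide(text: str, alphabet: Alphabet) -> Peptide:
    """Parse a sequence string (uppercase = L, lowercase = D) into a Peptide.

    Raises
    ------
    InvalidInputError
        If ``text`` is empty.
    UnknownResidueError
        If a character is not in ``alphabet``; names the 1-based position.
    """
    if not text:
        raise InvalidInputError("empty peptide string")
    indices = np.empty(len(text), dtype=np.intp)
    for pos, char in enumerate(text, start=1):
        if char not in alphabet:
            raise UnknownResidueError(char, pos)
        indices[pos - 1] = alphabet.lookup(char).type_index
    return Peptide(alphabet, indices)


def decode_peptide(p: Peptide) -> str:
    """Inverse of :func:`encode_peptide`."""
    chars = [p.alphabet.residues[i].char for i in p.type_indices]
    return "".join(chars)


def space_size(alphabet_size: int, length: int) -> int:
    """Exact number of distinct sequences: ``alphabet_size ** length``.

    Arbitrary-precision integer arithmetic; no floating point is involved, so
    counts like the 35^9 = 78 815 638 671 875 nonamer library are exact.
    """
    if alphabet_size < 1:
        raise InvalidInputError(f"alphabet_size must be >= 1, got {alphabet_size}")
    if length < 0:
        raise InvalidInputError(f"length must be >= 0, got {length}")
    return int(alphabet_size) ** int(length)


# -- plain-text sequence files ------------------------------------------


def read_sequences(path: str | Path, alphabet: Alphabet) -> list[Peptide]:
    """Read peptides from a text file: one sequence per line, or FASTA.

    The FASTA support is a nonstandard dialect in which lowercase letters are
    significant (D-residues) rather than masking.
    """
    peptides = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith((">", "#", ";")):
            continue
        peptides.append(encode_peptide(line, alphabet))
    return peptides


def write_sequences(path: str | Path, peptides: Iterable[Peptide]) -> None:
    Path(path).write_text("".join(f"{decode_peptide(p)}\n" for p in peptides))
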