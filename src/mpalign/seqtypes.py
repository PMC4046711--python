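"""Core domain types: biological sequences and pairwise alignments.

Coordinates are 1-based and inclusive throughout the public data model:
sequence ``x = x_1 x_2 ... x_L`` and an alignment is a set of index pairs
``(i, j)`` meaning residue ``x_i`` is aligned to residue ``y_j``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

PROTEIN_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
NUCLEOTIDE_ALPHABET = "ACGT"

#: ambiguity code -> compatible unambiguous residues
PROTEIN_AMBIGUITY = {
    "X": PROTEIN_ALPHABET,
    "B": "ND",
    "Z": "QE",
    "J": "IL",
}
NUCLEOTIDE_AMBIGUITY = {
    "N": "ACGT",
    "R": "AG",
    "Y": "CT",
    "S": "GC",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
}


def alphabet_for(alphabet_kind: str) -> str:
    if alphabet_kind == "protein":
        return PROTEIN_ALPHABET
    if alphabet_kind == "nucleotide":
        return NUCLEOTIDE_ALPHABET
    raise ValueError(f"unknown alphabet kind: {alphabet_kind!r}")


def ambiguity_for(alphabet_kind: str) -> dict[str, str]:
    return PROTEIN_AMBIGUITY if alphabet_kind == "protein" else NUCLEOTIDE_AMBIGUITY


@dataclass(frozen=True)
class BioSequence:
    """An identified residue string over a declared alphabet.

    Residues are canonicalized to upper case on construction.  Symbols outside
    the alphabet and its recognized ambiguity codes are rejected with a
    position-specific message; ``*`` and ``-`` are never legal in unaligned
    input.
    """

    id: str
    residues: str
    alphabet_kind: str = "protein"

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        legal = set(alphabet_for(self.alphabet_kind)) | set(
            ambiguity_for(self.alphabet_kind)
        )
        for pos, sym in enumerate(self.residues, start=1):
            if sym not in legal:
                raise ValueError(
                    f"sequence {self.id!r}: illegal {self.alphabet_kind} "
                    f"residue {sym!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i: int) -> str:
        """1-based residue access: ``seq[1]`` is the first residue."""
        if not 1 <= i <= len(self.residues):
            raise IndexError(f"position {i} outside [1, {len(self.residues)}]")
        return self.residues[i - 1]


@dataclass(frozen=True)
class PairwiseAlignment:
    """A monotone matching: aligned index pairs strictly increasing in both
    coordinates, plus the lengths (L, M) of the two sequences it refers to.

    Positions not covered by any pair are gaps.  The empty matching is a
    valid alignment (everything gapped).
    """

    pairs: tuple[tuple[int, int], ...]
    lengths: tuple[int, int]

    def __init__(
        self, pairs: Iterable[Sequence[int]], lengths: Sequence[int]
    ) -> None:
        tup = tuple((int(i), int(j)) for i, j in pairs)
        L, M = int(lengths[0]), int(lengths[1])
        prev_i, prev_j = 0, 0
        for i, j in tup:
            if not (1 <= i <= L and 1 <= j <= M):
                raise ValueError(
                    f"aligned pair ({i},{j}) outside [1,{L}]x[1,{M}]"
                )
            if not (i > prev_i and j > prev_j):
                raise ValueError(
                    f"aligned pairs must be strictly increasing in both "
                    f"coordinates; ({i},{j}) follows ({prev_i},{prev_j})"
                )
            prev_i, prev_j = i, j
        object.__setattr__(self, "pairs", tup)
        object.__setattr__(self, "lengths", (L, M))

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[int, int]) -> bool:
        return tuple(pair) in set(self.pairs)

    def pair_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(self.pairs)

    def transpose(self) -> "PairwiseAlignment":
        """Swap the roles of the two sequences."""
        return PairwiseAlignment(
            [(j, i) for i, j in self.pairs], (self.lengths[1], self.lengths[0])
        )
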