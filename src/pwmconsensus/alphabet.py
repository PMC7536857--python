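"""Ordered character alphabets for motif matrices.

An :class:`Alphabet` fixes the column order of a position weight matrix and,
for nucleotide alphabets, carries the strand-complement map and the IUPAC
ambiguity table used by the renderer (e.g. ``{C,G} -> S``, full set -> ``N``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "Alphabet",
    "DNA",
    "RNA",
    "PROTEIN",
    "infer_alphabet",
]

_DNA_CHARS = "ACGT"
_RNA_CHARS = "ACGU"
_PROTEIN_CHARS = "ACDEFGHIKLMNPQRSTVWY"

# Nucleotide ambiguity codes keyed by the unordered character subset.
_IUPAC_DNA: dict[frozenset[str], str] = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AC"): "M",
    frozenset("AG"): "R",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
    frozenset("ACG"): "V",
    frozenset("ACT"): "H",
    frozenset("AGT"): "D",
    frozenset("CGT"): "B",
    frozenset("ACGT"): "N",
}


def _u_substituted(table: dict[frozenset[str], str]) -> dict[frozenset[str], str]:
    out = {}
    for subset, code in table.items():
        out[frozenset("U" if c == "T" else c for c in subset)] = code
    return out


_IUPAC_RNA = _u_substituted(_IUPAC_DNA)


@dataclass(frozen=True)
class Alphabet:
    """Ordered set of distinct single characters over which a PWM is defined.

    Parameters
    ----------
    characters
        Ordered tuple of distinct single characters; length >= 2.
    kind
        One of ``dna``, ``rna``, ``protein``, ``custom``.
    complement_map
        Character involution for strand complementing (nucleotides only).
    iupac_table
        Map from character subset (frozenset) to a single ambiguity code
        (nucleotides only).
    """

    characters: tuple[str, ...]
    kind: str = "custom"
    complement_map: dict[str, str] | None = field(default=None, compare=False)
    iupac_table: dict[frozenset[str], str] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        chars = tuple(self.characters)
        if len(chars) < 2:
            raise ValueError("alphabet needs at least 2 characters")
        if len(set(chars)) != len(chars):
            raise ValueError(f"alphabet characters are not unique: {chars}")
        if any(len(c) != 1 for c in chars):
            raise ValueError("alphabet characters must be single characters")
        if self.kind not in ("dna", "rna", "protein", "custom"):
            raise ValueError(f"unknown alphabet kind {self.kind!r}")
        if self.complement_map is not None:
            for a, b in self.complement_map.items():
                if self.complement_map.get(b) != a:
                    raise ValueError("complement_map is not an involution")
                if a not in chars or b not in chars:
                    raise ValueError("complement_map references unknown character")
        object.__setattr__(self, "characters", chars)

    @property
    def size(self) -> int:
        return len(self.characters)

    def index(self, char: str) -> int:
        return self.characters.index(char)

    @property
    def is_nucleotide(self) -> bool:
        return self.kind in ("dna", "rna")

    def complement(self, char: str) -> str:
        if self.complement_map is None:
            raise ValueError(f"{self.kind} alphabet has no complement map")
        return self.complement_map[char]

    def reverse_complement(self, sequence: str) -> str:
        cmap = self.complement_map
        if cmap is None:
            raise ValueError(f"{self.kind} alphabet has no complement map")
        return "".join(cmap.get(c, c) for c in reversed(sequence))


DNA = Alphabet(
    tuple(_DNA_CHARS),
    kind="dna",
    complement_map={"A": "T", "T": "A", "C": "G", "G": "C"},
    iupac_table=_IUPAC_DNA,
)

RNA = Alphabet(
    tuple(_RNA_CHARS),
    kind="rna",
    complement_map={"A": "U", "U": "A", "C": "G", "G": "C"},
    iupac_table=_IUPAC_RNA,
)

PROTEIN = Alphabet(tuple(_PROTEIN_CHARS), kind="protein")


def infer_alphabet(characters: str | tuple[str, ...]) -> Alphabet:
    """Classify a character set as DNA, RNA, protein, or custom.

    Exact (unordered) character-set match decides dna/rna/protein; anything
    else becomes a custom alphabet keeping the given character order.
    """
    chars = tuple(c.upper() for c in characters)
    charset = set(chars)
    if charset == set(_DNA_CHARS):
        return DNA
    if charset == set(_RNA_CHARS):
        return RNA
    if charset == set(_PROTEIN_CHARS):
        return PROTEIN
    return Alphabet(chars, kind="custom")
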