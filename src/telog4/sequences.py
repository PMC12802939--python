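"""Ribonucleotide-substituted telomeric sequences.

The human telomeric repeat is TTAGGG.  The minimal intramolecular
G-quadruplex-forming construct is four tandem repeats, (TTAGGG)4, a 24-mer.
Constructs carrying a single ribonucleotide (rNMP) in place of the matching
deoxyribonucleotide are written in lowercase-r notation: an ``r`` immediately
before a base marks that base as ribose-sugared, e.g. ``TTArGGGTTAGGG...`` has
a riboguanosine at position 4.  The ``r`` consumes no sequence position, so a
construct named for position *p* has its substitution at index *p* of the
plain base string.

Within one TTAGGG repeat the six positions fall into structural classes that
govern how a substitution perturbs the quadruplex: the two thymines (T), the
loop adenine (A), and the first, second and third guanine of the tetrad-forming
run (G1, G2, G3).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "Sugar",
    "Residue",
    "TelomericSequence",
    "PositionClass",
    "SubstitutionSite",
    "SequenceParseError",
    "parse_sequence",
    "format_sequence",
    "classify_position",
    "read_sequence_table",
    "CANONICAL_REPEAT",
    "CANONICAL_LENGTH",
]

CANONICAL_REPEAT = "TTAGGG"
CANONICAL_LENGTH = 24

_VALID_BASES = frozenset("ACGT")


class SequenceParseError(ValueError):
    """Malformed lowercase-r sequence notation; carries the offending index."""

    def __init__(self, message: str, index: int):
        super().__init__(f"{message} (at character index {index})")
        self.index = index


class Sugar(enum.Enum):
    DEOXY = "deoxy"
    RIBO = "ribo"


class PositionClass(enum.Enum):
    """Structural class of a position within one TTAGGG repeat."""

    T = "T"
    A_LOOP = "A_loop"
    G1 = "G1"
    G2 = "G2"
    G3 = "G3"


#: offset within the repeat (0-based) -> structural class
_OFFSET_CLASS = {
    0: PositionClass.T,
    1: PositionClass.T,
    2: PositionClass.A_LOOP,
    3: PositionClass.G1,
    4: PositionClass.G2,
    5: PositionClass.G3,
}


@dataclass(frozen=True)
class Residue:
    base: str
    sugar: Sugar = Sugar.DEOXY

    def __post_init__(self):
        if self.base not in _VALID_BASES:
            raise ValueError(f"invalid base {self.base!r}")


@dataclass(frozen=True)
class TelomericSequence:
    """An oligonucleotide with at most one ribose-sugared residue."""

    name: str
    residues: tuple[Residue, ...]

    def __post_init__(self):
        n_ribo = sum(1 for r in self.residues if r.sugar is Sugar.RIBO)
        if n_ribo > 1:
            raise ValueError(f"at most one ribonucleotide allowed, found {n_ribo}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def bases(self) -> str:
        return "".join(r.base for r in self.residues)

    @property
    def ribo_position(self) -> Optional[int]:
        """1-based position of the ribonucleotide, or None."""
        for i, r in enumerate(self.residues):
            if r.sugar is Sugar.RIBO:
                return i + 1
        return None

    @property
    def is_canonical(self) -> bool:
        """True when the base string is exactly (TTAGGG)4."""
        return self.bases == CANONICAL_REPEAT * 4


@dataclass(frozen=True)
class SubstitutionSite:
    """Location of the single rNMP within a canonical 24-mer.

    ``position`` is 1-based into the 24-mer (matching construct names:
    TELR10 has position 10); ``repeat_index`` runs 1-4.
    """

    position: int
    repeat_index: int
    position_class: PositionClass

    @classmethod
    def from_position(cls, position: int) -> "SubstitutionSite":
        if not 1 <= position <= CANONICAL_LENGTH:
            raise ValueError(f"position {position} outside 1..{CANONICAL_LENGTH}")
        offset = (position - 1) % 6
        return cls(
            position=position,
            repeat_index=(position - 1) // 6 + 1,
            position_class=_OFFSET_CLASS[offset],
        )


def parse_sequence(text: str, name: str = "") -> TelomericSequence:
    """Parse lowercase-r notation into a :class:`TelomericSequence`.

    ``r`` is a prefix modifier: it marks the immediately following base as
    ribose-sugared and occupies no sequence position.  At most one ``r`` is
    allowed; it must be directly followed by a base character.
    """
    residues: list[Residue] = []
    seen_ribo = False
    pending_ribo = False
    for i, ch in enumerate(text.strip()):
        if ch == "r":
            if pending_ribo:
                raise SequenceParseError("'r' may not follow another 'r'", i)
            if seen_ribo:
                raise SequenceParseError("more than one 'r' marker", i)
            pending_ribo = True
            seen_ribo = True
        elif ch in _VALID_BASES:
            residues.append(Residue(ch, Sugar.RIBO if pending_ribo else Sugar.DEOXY))
            pending_ribo = False
        else:
            raise SequenceParseError(f"invalid character {ch!r}", i)
    if pending_ribo:
        raise SequenceParseError("trailing 'r' with no base", len(text.strip()) - 1)
    return TelomericSequence(name=name, residues=tuple(residues))


def format_sequence(seq: TelomericSequence) -> str:
    """Inverse of :func:`parse_sequence` (exact round-trip)."""
    out = []
    for r in seq.residues:
        if r.sugar is Sugar.RIBO:
            out.append("r")
        out.append(r.base)
    return "".join(out)


def classify_position(seq: TelomericSequence) -> Optional[SubstitutionSite]:
    """Map the sequence's substitution position to its structural class.

    Returns None for an unsubstituted sequence.  Requires the canonical
    (TTAGGG)4 24-mer; anything else is an error because repeat offsets are
    undefined for it.
    """
    if len(seq) != CANONICAL_LENGTH or not seq.is_canonical:
        raise ValueError(
            f"position classes are defined only for the canonical "
            f"(TTAGGG)4 24-mer; got {seq.bases!r}"
        )
    pos = seq.ribo_position
    if pos is None:
        return None
    return SubstitutionSite.from_position(pos)


def read_sequence_table(path) -> list[TelomericSequence]:
    """Read sequences from plain text: one per line, optional leading
    tab-separated name column; blank lines and '#' comments skipped."""
    seqs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "\t" in line:
                name, text = line.split("\t", 1)
            else:
                name, text = "", line
            seqs.append(parse_sequence(text.strip(), name=name.strip()))
    return seqs
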