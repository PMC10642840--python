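"""Physical DNA model and string-level primitives.

The central type is :class:`Polynucleotide`, which captures the state of a DNA
molecule the way a bench scientist describes it: the fully duplexed region as
the coding (top) strand, single-stranded overhangs at either end, the 5'-end
chemistry of both strands, strandedness, and circularity.

Conventions used throughout the package:

* Coordinates are 0-based, half-open, on the top strand.
* Sequences are normalised to uppercase on ingest.
* Overhang strings are always written in coding-strand (top) sense, regardless
  of which physical strand protrudes; the protrusion kind flag records whether
  the single-stranded extension is a 5' or 3' protrusion.
* For a linear duplex the "virtual full-length top strand" is
  ``ext5 + sequence + ext3``; the total base count of the molecule (counting
  each overhang once) is the length of that string.
* Circular molecules store the full circle in ``sequence`` with blunt, empty
  extensions and no end chemistry; all comparisons are rotation-aware.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

from .errors import AlphabetError

IUPAC_SETS = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class Protrusion(str, enum.Enum):
    """Which strand protrudes in a single-stranded overhang."""

    FIVE_PRIME = "five_prime"
    THREE_PRIME = "three_prime"
    BLUNT = "blunt"


class Chem(str, enum.Enum):
    """5'-terminus chemistry; ligase requires a phosphate to seal a nick."""

    HYDROXYL = "hydroxyl"
    PHOSPHATE = "phosphate"


def check_iupac(seq: str, context: str = "sequence") -> str:
    """Uppercase *seq* and verify it only contains IUPAC DNA codes."""
    up = seq.upper()
    for i, ch in enumerate(up):
        if ch not in IUPAC_SETS:
            raise AlphabetError(
                f"Non-IUPAC character {ch!r} at position {i} in {context}"
            )
    return up


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string (degenerate codes included)."""
    up = check_iupac(seq)
    return up.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Polynucleotide:
    """Physical state of one DNA species.

    Parameters
    ----------
    sequence:
        Top strand of the fully duplexed region (dsDNA), the whole molecule
        (ssDNA oligo), or the whole circle (circular DNA).
    ext5, ext3:
        Overhang sequences at the left and right ends, in coding-strand sense.
    ext5_kind, ext3_kind:
        Protrusion kind of each overhang.
    mod_ext5:
        Chemistry of the left-end top-strand 5' terminus.
    mod_ext3:
        Chemistry of the right-end bottom-strand 5' terminus.
    """

    sequence: str
    ext5: str = ""
    ext3: str = ""
    ext5_kind: Protrusion = Protrusion.BLUNT
    ext3_kind: Protrusion = Protrusion.BLUNT
    mod_ext5: Chem | None = Chem.HYDROXYL
    mod_ext3: Chem | None = Chem.HYDROXYL
    is_double_stranded: bool = True
    is_circular: bool = False
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "sequence", check_iupac(self.sequence, f"sequence of {self.name or 'molecule'}"))
        object.__setattr__(self, "ext5", check_iupac(self.ext5, f"ext5 of {self.name or 'molecule'}"))
        object.__setattr__(self, "ext3", check_iupac(self.ext3, f"ext3 of {self.name or 'molecule'}"))
        from .errors import SchemaError

        for ext, kind, label in ((self.ext5, self.ext5_kind, "ext5"), (self.ext3, self.ext3_kind, "ext3")):
            if (kind is Protrusion.BLUNT) != (ext == ""):
                raise SchemaError(
                    f"{self.name or 'molecule'}: {label} must be empty iff blunt "
                    f"(got {ext!r} with kind {kind.value})"
                )
        if self.is_circular:
            if self.ext5 or self.ext3:
                raise SchemaError(f"{self.name or 'molecule'}: circular DNA cannot carry overhangs")
            if self.mod_ext5 is not None or self.mod_ext3 is not None:
                raise SchemaError(f"{self.name or 'molecule'}: circular DNA has no end chemistry")
            if not self.is_double_stranded:
                raise SchemaError(f"{self.name or 'molecule'}: circular single strands are unsupported")
        if not self.is_double_stranded and (self.ext5 or self.ext3):
            raise SchemaError(f"{self.name or 'molecule'}: a single strand has no duplex overhangs")

    def __len__(self) -> int:
        """Total base count, counting each overhang once."""
        return len(self.ext5) + len(self.sequence) + len(self.ext3)

    @property
    def top_strand(self) -> str:
        """Virtual full-length top strand ``ext5 + sequence + ext3``."""
        return self.ext5 + self.sequence + self.ext3

    def renamed(self, name: str) -> "Polynucleotide":
        return replace(self, name=name)

    def reverse_complemented(self) -> "Polynucleotide":
        """The same molecule viewed from the other strand (ends swap)."""
        if not self.is_double_stranded:
            return replace(self, sequence=reverse_complement(self.sequence))
        return replace(
            self,
            sequence=reverse_complement(self.sequence),
            ext5=reverse_complement(self.ext3),
            ext3=reverse_complement(self.ext5),
            ext5_kind=self.ext3_kind,
            ext3_kind=self.ext5_kind,
            mod_ext5=self.mod_ext3,
            mod_ext3=self.mod_ext5,
        )

    @classmethod
    def oligo(cls, sequence: str, name: str = "", phosphorylated: bool = False) -> "Polynucleotide":
        return cls(
            sequence=sequence,
            is_double_stranded=False,
            mod_ext5=Chem.PHOSPHATE if phosphorylated else Chem.HYDROXYL,
            mod_ext3=Chem.HYDROXYL,
            name=name,
        )

    @classmethod
    def blunt_dsdna(cls, sequence: str, name: str = "") -> "Polynucleotide":
        return cls(sequence=sequence, name=name)

    @classmethod
    def plasmid(cls, sequence: str, name: str = "") -> "Polynucleotide":
        return cls(
            sequence=sequence,
            is_circular=True,
            mod_ext5=None,
            mod_ext3=None,
            name=name,
        )


def iupac_match(pattern_char: str, target_char: str) -> bool:
    """True iff the IUPAC base sets of the two letters intersect."""
    return bool(IUPAC_SETS[pattern_char] & IUPAC_SETS[target_char])


def _window_matches(pattern: str, window: str) -> bool:
    return len(window) == len(pattern) and all(
        iupac_match(p, t) for p, t in zip(pattern, window)
    )


def find_sites(pattern: str, target: "Polynucleotide | str") -> list[tuple[int, str]]:
    """Locate all matches of an IUPAC *pattern* on both strands of *target*.

    Returns ``(position, strand)`` pairs where *position* is the 0-based
    top-strand index of the match window's left edge and *strand* is ``'+'``
    or ``'-'``.  A minus-strand match means the reverse complement of the
    pattern occurs in the top strand at that window.  For circular targets,
    windows crossing the origin are reported (positions are taken mod the
    circle length).  Only the duplexed region is searched for dsDNA.
    """
    if not pattern:
        raise ValueError("pattern must be non-empty")
    pat = check_iupac(pattern, "pattern")
    if isinstance(target, Polynucleotide):
        seq = target.sequence
        circular = target.is_circular
    else:
        seq = check_iupac(target, "target")
        circular = False
    m = len(pat)
    n = len(seq)
    if n == 0:
        return []
    search_space = seq + seq[: m - 1] if circular else seq
    rc_pat = reverse_complement(pat)
    hits: list[tuple[int, str]] = []
    for i in range(len(search_space) - m + 1):
        window = search_space[i : i + m]
        pos = i % n if circular else i
        if _window_matches(pat, window):
            hits.append((pos, "+"))
        if _window_matches(rc_pat, window):
            hits.append((pos, "-"))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def _rotations(seq: str):
    for i in range(len(seq)):
        yield seq[i:] + seq[:i]


def equivalent(a: Polynucleotide, b: Polynucleotide) -> bool:
    """True iff *a* and *b* describe the same physical molecule.

    Circular DNAs compare equal up to rotation and strand flip; linear DNAs
    compare exactly, or exactly after reverse complementing the whole
    molecule (a tube of DNA has no intrinsic orientation).
    """
    if a.is_circular != b.is_circular or a.is_double_stranded != b.is_double_stranded:
        return False
    if a.is_circular:
        if len(a.sequence) != len(b.sequence):
            return False
        if not a.sequence:
            return True
        doubled = b.sequence + b.sequence
        return a.sequence in doubled or reverse_complement(a.sequence) in doubled
    def state(p: Polynucleotide):
        return (p.sequence, p.ext5, p.ext3, p.ext5_kind, p.ext3_kind, p.mod_ext5, p.mod_ext3)
    return state(a) == state(b) or state(a) == state(b.reverse_complemented())


def rotated(p: Polynucleotide, offset: int) -> Polynucleotide:
    """Rotate a circular molecule so the stored sequence starts at *offset*."""
    if not p.is_circular:
        raise ValueError("only circular molecules can be rotated")
    n = len(p.sequence)
    off = offset % n if n else 0
    return replace(p, sequence=p.sequence[off:] + p.sequence[:off])
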