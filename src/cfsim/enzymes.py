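"""Restriction-enzyme knowledge base.

Enzyme records are loaded from a flat text file in the REBASE style: one
enzyme per line, ``name  site``, where the site carries its cut geometry
either as a caret within the recognition sequence (``G^AATTC``) or as a
``(top/bottom)`` offset pair counted from the 3' end of the recognition
sequence (``GGTCTC(1/5)``), the notation REBASE uses for enzymes that cut
outside their site.

Cut offsets are stored relative to the recognition start on the top strand:
``cut_top`` is where the top strand is severed, ``cut_bottom`` where the
bottom strand is.  ``cut_top < cut_bottom`` leaves a 5' protrusion,
``cut_top > cut_bottom`` a 3' protrusion, equality a blunt end.
"""

from __future__ import annotations

import difflib
import io
import re
from dataclasses import dataclass
from importlib import resources

from .dna import check_iupac
from .errors import EnzymeFormatError, UnknownEnzymeError

_REBASE_RE = re.compile(r"^([A-Z]+)\((-?\d+)/(-?\d+)\)$", re.IGNORECASE)


@dataclass(frozen=True)
class RestrictionEnzyme:
    name: str
    recognition: str  # IUPAC pattern
    cut_top: int      # top-strand cut offset from recognition start
    cut_bottom: int   # bottom-strand cut offset from recognition start

    @property
    def is_type_iis(self) -> bool:
        """Cuts outside its recognition site (both offsets beyond the pattern)."""
        m = len(self.recognition)
        return not (0 <= self.cut_top < m) and not (0 <= self.cut_bottom < m)

    @property
    def overhang_length(self) -> int:
        return abs(self.cut_top - self.cut_bottom)


def parse_site(site: str) -> tuple[str, int, int]:
    """Parse caret or ``(a/b)`` cut notation into (recognition, cut_top, cut_bottom)."""
    m = _REBASE_RE.match(site)
    if m:
        recognition = check_iupac(m.group(1), "recognition site")
        a, b = int(m.group(2)), int(m.group(3))
        return recognition, len(recognition) + a, len(recognition) + b
    if "^" in site:
        if site.count("^") != 1:
            raise EnzymeFormatError(f"Multiple carets in site {site!r}")
        cut_top = site.index("^")
        recognition = check_iupac(site.replace("^", ""), "recognition site")
        # Caret notation is used for within-site cutters, which are
        # palindromic; the bottom cut mirrors the top cut.
        return recognition, cut_top, len(recognition) - cut_top
    raise EnzymeFormatError(f"Unrecognised cut notation in site {site!r}")


class EnzymeTable:
    """Case-insensitive name -> :class:`RestrictionEnzyme` mapping."""

    def __init__(self, enzymes: dict[str, RestrictionEnzyme] | None = None):
        self._by_key: dict[str, RestrictionEnzyme] = {}
        for enz in (enzymes or {}).values():
            self.add(enz)

    def add(self, enz: RestrictionEnzyme) -> None:
        self._by_key[enz.name.lower()] = enz

    def __len__(self) -> int:
        return len(self._by_key)

    def __contains__(self, name: str) -> bool:
        return name.lower() in self._by_key

    def names(self) -> list[str]:
        return sorted(e.name for e in self._by_key.values())

    def lookup(self, name: str) -> RestrictionEnzyme:
        key = name.lower()
        if key in self._by_key:
            return self._by_key[key]
        suggestions = difflib.get_close_matches(key, list(self._by_key), n=3, cutoff=0.6)
        raise UnknownEnzymeError(name, [self._by_key[s].name for s in suggestions])


def load_enzyme_table(stream) -> EnzymeTable:
    """Load an enzyme table from a text stream (``name  site`` per line)."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    table = EnzymeTable()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise EnzymeFormatError(f"Line {lineno}: expected 'name site', got {line!r}")
        name, site = parts
        try:
            recognition, cut_top, cut_bottom = parse_site(site)
        except EnzymeFormatError as exc:
            raise EnzymeFormatError(f"Line {lineno}: {exc}") from None
        table.add(RestrictionEnzyme(name, recognition, cut_top, cut_bottom))
    return table


def default_table() -> EnzymeTable:
    """The bundled table of common cloning enzymes."""
    text = resources.files("cfsim.data").joinpath("enzymes.tsv").read_text()
    return load_enzyme_table(text)
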