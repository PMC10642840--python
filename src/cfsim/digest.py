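"""Restriction digestion (cut to completion) and sticky-end ligation.

A concrete cut event is a pair of phosphodiester scissions, one per strand,
expressed in top-strand coordinates: ``(top_cut, bottom_cut)``.  The bases
between the two scissions become the single-stranded overhang shared by the
two product ends.  ``top_cut < bottom_cut`` leaves 5' protrusions on both
product ends, ``top_cut > bottom_cut`` 3' protrusions, equality blunt ends.
Freshly cut 5' termini carry phosphates (the enzyme leaves them); the outer
ends of a linear parent keep whatever chemistry they had.

Digestion means cut to completion: all site positions are computed on the
intact parent and applied at once, so partial digests are not modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .dna import Chem, Polynucleotide, Protrusion, find_sites, reverse_complement
from .enzymes import EnzymeTable, RestrictionEnzyme
from .errors import DigestError, LigationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CutEvent:
    """One double-strand scission, in parent top-strand coordinates."""

    top_cut: int
    bottom_cut: int
    enzyme_index: int  # position of the enzyme in the digest's enzyme list

    @property
    def lo(self) -> int:
        return min(self.top_cut, self.bottom_cut)

    @property
    def hi(self) -> int:
        return max(self.top_cut, self.bottom_cut)

    @property
    def kind(self) -> Protrusion:
        if self.top_cut < self.bottom_cut:
            return Protrusion.FIVE_PRIME
        if self.top_cut > self.bottom_cut:
            return Protrusion.THREE_PRIME
        return Protrusion.BLUNT


def _site_cut(enzyme: RestrictionEnzyme, pos: int, strand: str) -> tuple[int, int]:
    """Map a recognition match to (top_cut, bottom_cut) in parent coordinates.

    For a minus-strand site the enzyme reads the bottom strand, so its
    top-strand cut lands on our bottom strand and the offsets count down
    from the right edge of the match window.
    """
    m = len(enzyme.recognition)
    if strand == "+":
        return pos + enzyme.cut_top, pos + enzyme.cut_bottom
    return pos + m - enzyme.cut_bottom, pos + m - enzyme.cut_top


def _collect_events(target: Polynucleotide, enzymes: list[RestrictionEnzyme]) -> list[CutEvent]:
    n = len(target.sequence)
    events: dict[tuple[int, int], CutEvent] = {}
    for idx, enz in enumerate(enzymes):
        sites = find_sites(enz.recognition, target)
        if not sites:
            log.warning("%s has no site in %s", enz.name, target.name or "substrate")
        for pos, strand in sites:
            top, bottom = _site_cut(enz, pos, strand)
            if target.is_circular:
                # Anchor the event at lo mod n so wrap-around cuts are unique.
                shift = min(top, bottom) % n - min(top, bottom)
                top, bottom = top + shift, bottom + shift
            else:
                if min(top, bottom) < 0 or max(top, bottom) > n:
                    # Type IIS site too close to an end: the scissile bond
                    # does not exist on this substrate.
                    continue
            key = (top, bottom)
            if key not in events:
                events[key] = CutEvent(top, bottom, idx)
    out = sorted(events.values(), key=lambda e: (e.lo, e.hi))
    for a, b in zip(out, out[1:]):
        if b.lo < a.hi:
            raise DigestError(
                f"Overlapping cut sites at {a.lo}..{a.hi} and {b.lo}..{b.hi} "
                f"in {target.name or 'substrate'}"
            )
    if target.is_circular and len(out) > 1 and out[-1].hi - n > out[0].lo:
        raise DigestError(
            f"Overlapping cut sites across the origin in {target.name or 'substrate'}"
        )
    return out


def cut_all(target: Polynucleotide, enzymes: list[RestrictionEnzyme]) -> list[Polynucleotide]:
    """Digest *target* to completion with every enzyme in *enzymes*.

    Returns fragments ordered left-to-right for a linear parent.  For a
    circular parent, fragment 0 starts at the first cut of the first enzyme
    in the list, matching the fragment-index convention of ``fragSelect``.
    """
    if not target.is_double_stranded:
        raise DigestError(
            f"Cannot digest single-stranded DNA {target.name or 'substrate'}"
        )
    events = _collect_events(target, enzymes)
    seq = target.sequence
    n = len(seq)
    if not events:
        return [target]

    def overhang(ev: CutEvent) -> str:
        if ev.hi <= n:
            return seq[ev.lo : ev.hi]
        return (seq + seq)[ev.lo : ev.hi]  # circular wrap

    if target.is_circular:
        first_enz = min(ev.enzyme_index for ev in events)
        start_i = min(
            (i for i, ev in enumerate(events) if ev.enzyme_index == first_enz),
            key=lambda i: events[i].lo,
        )
        ordered = events[start_i:] + events[:start_i]
        doubled = seq + seq
        fragments = []
        k = len(ordered)
        for i, ev in enumerate(ordered):
            nxt = ordered[(i + 1) % k]
            start = ev.hi
            if k == 1:
                end = ev.lo + n  # single cut linearises the whole circle
            else:
                end = nxt.lo
                if end < start:
                    end += n
            fragments.append(
                Polynucleotide(
                    sequence=doubled[start:end],
                    ext5=overhang(ev),
                    ext3=overhang(nxt),
                    ext5_kind=ev.kind,
                    ext3_kind=nxt.kind,
                    mod_ext5=Chem.PHOSPHATE,
                    mod_ext3=Chem.PHOSPHATE,
                    name=f"{target.name}.frag{i}" if target.name else f"frag{i}",
                )
            )
        return fragments

    fragments = []
    prev: CutEvent | None = None
    boundaries = [*events, None]
    for i, ev in enumerate(boundaries):
        start = prev.hi if prev is not None else 0
        end = ev.lo if ev is not None else n
        fragments.append(
            Polynucleotide(
                sequence=seq[start:end],
                ext5=overhang(prev) if prev is not None else target.ext5,
                ext3=overhang(ev) if ev is not None else target.ext3,
                ext5_kind=prev.kind if prev is not None else target.ext5_kind,
                ext3_kind=ev.kind if ev is not None else target.ext3_kind,
                mod_ext5=Chem.PHOSPHATE if prev is not None else target.mod_ext5,
                mod_ext3=Chem.PHOSPHATE if ev is not None else target.mod_ext3,
                name=f"{target.name}.frag{i}" if target.name else f"frag{i}",
            )
        )
        prev = ev
    return fragments


def simulate_digest(
    dna: Polynucleotide,
    enzyme_names: list[str],
    frag_select: int,
    table: EnzymeTable,
    product_name: str = "",
) -> Polynucleotide:
    """Digest *dna* and return the fragment at index *frag_select*."""
    enzymes = [table.lookup(name) for name in enzyme_names]
    fragments = cut_all(dna, enzymes)
    lengths = ", ".join(f"[{i}] {len(f)} bp" for i, f in enumerate(fragments))
    log.info(
        "Digest of %s with %s yields %d fragment(s): %s",
        dna.name or "substrate", "+".join(e.name for e in enzymes), len(fragments), lengths,
    )
    if frag_select >= len(fragments):
        raise DigestError(
            f"fragSelect {frag_select} out of range: digest produced "
            f"{len(fragments)} fragment(s): {lengths}"
        )
    frag = fragments[frag_select]
    return frag.renamed(product_name) if product_name else frag


# ---------------------------------------------------------------------------
# Ligation
# ---------------------------------------------------------------------------

def ends_compatible(
    left_ext: str, left_kind: Protrusion, right_ext: str, right_kind: Protrusion
) -> bool:
    """Can a fragment's right end anneal to another fragment's left end?

    In top-strand sense the two ends of one cut carry the *same* overhang
    string, so annealing requires string equality and matching protrusion
    kind (or two blunt ends).  Chemistry is checked separately at ligation.
    """
    if left_kind is Protrusion.BLUNT and right_kind is Protrusion.BLUNT:
        return True
    return left_kind == right_kind and left_ext == right_ext


def _joinable(a: Polynucleotide, b: Polynucleotide) -> bool:
    """Can ligase seal a's right end to b's left end (sticky ends + phosphates)?"""
    if not ends_compatible(a.ext3, a.ext3_kind, b.ext5, b.ext5_kind):
        return False
    # The junction seals two nicks: b's top-strand 5' end and a's
    # bottom-strand 5' end must both be phosphorylated.
    return a.mod_ext3 is Chem.PHOSPHATE and b.mod_ext5 is Chem.PHOSPHATE


def _join(a: Polynucleotide, b: Polynucleotide) -> Polynucleotide:
    return Polynucleotide(
        sequence=a.sequence + a.ext3 + b.sequence,
        ext5=a.ext5,
        ext3=b.ext3,
        ext5_kind=a.ext5_kind,
        ext3_kind=b.ext3_kind,
        mod_ext5=a.mod_ext5,
        mod_ext3=b.mod_ext3,
        name=a.name,
    )


def _describe_end(frag: Polynucleotide, side: str) -> str:
    ext = frag.ext5 if side == "left" else frag.ext3
    kind = frag.ext5_kind if side == "left" else frag.ext3_kind
    mod = frag.mod_ext5 if side == "left" else frag.mod_ext3
    return f"{frag.name or 'fragment'}:{side}({ext or 'blunt'}/{kind.value}/{mod.value if mod else '-'})"


def _try_circularize(frag: Polynucleotide) -> Polynucleotide | None:
    if not _joinable(frag, frag):
        return None
    return Polynucleotide.plasmid(frag.sequence + frag.ext3, name=frag.name)


def simulate_ligate(fragments: list[Polynucleotide], product_name: str = "") -> Polynucleotide:
    """Ligate fragments pairwise until a single molecule remains.

    Fragments may join in either orientation.  If the final molecule's own
    ends are compatible (phosphorylated, matching sticky ends) it is closed
    into a circle with the overhang absorbed into the sequence; otherwise it
    stays linear.  An end that could join two different partners makes the
    outcome ambiguous and is reported as an error, as is a mixture that
    cannot be reduced to one molecule.
    """
    if not fragments:
        raise LigationError("Ligate needs at least one input fragment")
    for frag in fragments:
        if not frag.is_double_stranded:
            raise LigationError(f"Cannot ligate single-stranded DNA {frag.name or 'fragment'}")
        if frag.is_circular:
            raise LigationError(f"Circular DNA {frag.name or 'fragment'} cannot be ligated")
    frags = list(fragments)
    while len(frags) > 1:
        # Pre-pass: every end must have at most one possible partner end,
        # otherwise more than one distinct assembly is possible.
        right_partners: dict[int, list[tuple[int, Polynucleotide]]] = {}
        for i, a in enumerate(frags):
            rp, lp = [], []
            for j, b in enumerate(frags):
                if i == j:
                    continue
                flipped = b.reverse_complemented()
                if _joinable(a, b):
                    rp.append((j, b))
                if _joinable(a, flipped):
                    rp.append((j, flipped))
                if _joinable(b, a):
                    lp.append((j, "n"))
                if _joinable(flipped, a):
                    lp.append((j, "f"))
            if len(rp) > 1:
                raise LigationError(
                    f"Ambiguous ligation: {_describe_end(a, 'right')} matches "
                    f"{len(rp)} different partner ends"
                )
            if len(lp) > 1:
                raise LigationError(
                    f"Ambiguous ligation: {_describe_end(a, 'left')} matches "
                    f"{len(lp)} different partner ends"
                )
            right_partners[i] = rp
        joined = None
        for i, a in enumerate(frags):
            if right_partners[i]:
                j, b = right_partners[i][0]
                joined = (i, j, _join(a, b))
                break
        if joined is None:
            ends = [_describe_end(f, s) for f in frags for s in ("left", "right")]
            raise LigationError(
                f"Ligation cannot proceed: {len(frags)} fragments remain with no "
                f"compatible phosphorylated end pair. Ends: {'; '.join(ends)}"
            )
        i, j, merged = joined
        frags = [f for k, f in enumerate(frags) if k not in (i, j)] + [merged]
    final = frags[0]
    circle = _try_circularize(final)
    product = circle if circle is not None else final
    return product.renamed(product_name) if product_name else product
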