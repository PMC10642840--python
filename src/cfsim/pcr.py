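"""PCR product prediction.

Two routes, mirroring how validation tools handle the problem in practice:

* **Fast exact path** — used when a single template and two oligos are
  present and each oligo's 3'-terminal 18 bases match the template exactly,
  uniquely, and in convergent orientation.  The product is then pure string
  surgery: forward oligo (with any 5' tail) + intervening template + reverse
  complement of the reverse oligo.
* **Mechanistic path** — a fallback that mimics pairwise annealing and
  extension.  Candidate sites are seeded by an exact match of the oligo's
  3'-terminal six bases, extended 5'-ward as an ungapped alignment anchored
  at the 3' end, and kept when the estimated melting temperature of the
  annealed duplex clears a threshold.  This path handles mutagenic primers
  with internal mismatches, and reports multi-site ambiguity as an error.

Products are linear, blunt, double-stranded; each 5' end inherits the
chemistry of the oligo that primed that strand.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dna import Chem, Polynucleotide, reverse_complement
from .errors import AmbiguousProductError, NoProductError, PCRError, SizeMismatchError

#: 3'-terminal identity required by the fast exact path.
FAST_PATH_ANNEAL_LENGTH = 18
#: Exact 3'-terminal seed required before mechanistic extension.
SEED_LENGTH = 6
#: Minimum estimated Tm (degC) for a mechanistic site to be accepted.
DEFAULT_TM_THRESHOLD = 45.0
#: Tm penalty per mismatched position in the annealed window.
MISMATCH_PENALTY = 5.0
#: Inputs at or above this length are never treated as primers.
MAX_PRIMER_LENGTH = 100


@dataclass(frozen=True)
class AnnealSite:
    """A primer binding site on a template.

    ``template_position`` is the top-strand index of the base pairing the
    oligo's 3'-terminal base.  On ``+`` the polymerase extends rightward,
    on ``-`` leftward (in top-strand coordinates).
    """

    template_position: int
    strand: str
    annealed_length: int  # matched bases in the aligned window
    melting_temp: float


def estimate_tm(window_length: int, gc_count: int, mismatches: int = 0) -> float:
    """GC-corrected Wallace-type melting-temperature estimate (degC)."""
    if window_length == 0:
        return float("-inf")
    tm = 64.9 + 41.0 * (gc_count - 16.4) / window_length
    return tm - MISMATCH_PENALTY * mismatches


def find_anneal_sites(
    oligo: Polynucleotide,
    template: Polynucleotide,
    tm_threshold: float = DEFAULT_TM_THRESHOLD,
) -> list[AnnealSite]:
    """All sites where *oligo* can prime synthesis on *template*.

    Both strands are searched; circular templates are searched across the
    origin.  A site requires the oligo's 3'-terminal six bases to match the
    template exactly; the rest of the oligo is aligned without gaps and the
    site is kept iff the estimated Tm of the annealed duplex clears
    *tm_threshold*.
    """
    o = oligo.sequence
    t = template.sequence
    n = len(t)
    if len(o) < SEED_LENGTH or n < SEED_LENGTH:
        return []
    circ = template.is_circular
    seed = o[-SEED_LENGTH:]
    rc_seed = reverse_complement(seed)
    space = t + t[: SEED_LENGTH - 1] if circ else t
    doubled = t + t

    def alignment(paired: str) -> tuple[int, int, int, int]:
        """Compare the oligo 3'-anchored against the template bases it pairs
        (both strings 5'->3' in the oligo's frame).  Also reports the length
        of the perfectly matched run at the 3' end."""
        k = len(paired)
        matches = gc = 0
        for oc, tc in zip(o[-k:], paired):
            if oc == tc:
                matches += 1
                if oc in "GC":
                    gc += 1
        run3 = 0
        for oc, tc in zip(reversed(o[-k:]), reversed(paired)):
            if oc != tc:
                break
            run3 += 1
        return k, matches, gc, run3

    def accepted(tm: float, run3: int) -> bool:
        # A perfect 3'-terminal match as long as the fast-path criterion is
        # always a usable primer, whatever its base composition.
        return tm >= tm_threshold or run3 >= FAST_PATH_ANNEAL_LENGTH

    sites: dict[tuple[int, str], AnnealSite] = {}
    for i in range(len(space) - SEED_LENGTH + 1):
        window6 = space[i : i + SEED_LENGTH]
        # '+' site: oligo matches the top strand; 3' base at index i+5.
        if window6 == seed:
            pos = (i + SEED_LENGTH - 1) % n if circ else i + SEED_LENGTH - 1
            k = min(len(o), pos + 1) if not circ else min(len(o), n)
            if circ:
                start = (pos + 1 - k) % n
                paired = doubled[start : start + k]
            else:
                paired = t[pos + 1 - k : pos + 1]
            k, matches, gc, run3 = alignment(paired)
            tm = estimate_tm(k, gc, k - matches)
            if accepted(tm, run3):
                sites.setdefault((pos, "+"), AnnealSite(pos, "+", matches, tm))
        # '-' site: oligo matches the bottom strand; 3' base pairs index i.
        if window6 == rc_seed:
            pos = i % n if circ else i
            k = min(len(o), n - pos) if not circ else min(len(o), n)
            if circ:
                paired_top = doubled[pos : pos + k]
            else:
                paired_top = t[pos : pos + k]
            k, matches, gc, run3 = alignment(reverse_complement(paired_top))
            tm = estimate_tm(k, gc, k - matches)
            if accepted(tm, run3):
                sites.setdefault((pos, "-"), AnnealSite(pos, "-", matches, tm))
    return list(sites.values())


def _count_unique(seq: str, sub: str, circular: bool) -> list[int]:
    """Start positions of *sub* in *seq* (circular-aware, mod length)."""
    space = seq + seq[: len(sub) - 1] if circular else seq
    n = len(seq)
    hits = []
    start = 0
    while True:
        i = space.find(sub, start)
        if i == -1:
            break
        hits.append(i % n if circular else i)
        start = i + 1
    return sorted(set(hits))


def _product_from_positions(
    fwd: Polynucleotide,
    rev: Polynucleotide,
    template: Polynucleotide,
    fwd_3end: int,
    rev_3end: int,
) -> str | None:
    """Top strand of the amplicon, or None if the geometry is not convergent."""
    t = template.sequence
    n = len(t)
    if template.is_circular:
        gap_start = (fwd_3end + 1) % n
        span = (rev_3end - gap_start) % n
        middle = (t * 2)[gap_start : gap_start + span]
    else:
        if rev_3end <= fwd_3end:
            return None
        middle = t[fwd_3end + 1 : rev_3end]
    return fwd.sequence + middle + reverse_complement(rev.sequence)


def fast_pcr(
    fwd: Polynucleotide, rev: Polynucleotide, template: Polynucleotide
) -> str | None:
    """The exact 18 bp path. Returns the product top strand, or None when the
    preconditions (exact, unique, convergent 3'-terminal 18-mers) fail."""
    k = FAST_PATH_ANNEAL_LENGTH
    if len(fwd.sequence) < k or len(rev.sequence) < k:
        return None
    t = template.sequence
    circ = template.is_circular
    f18 = fwd.sequence[-k:]
    r18rc = reverse_complement(rev.sequence[-k:])
    f_fwd = _count_unique(t, f18, circ)
    f_rev = _count_unique(t, reverse_complement(f18), circ)
    r_fwd = _count_unique(t, r18rc, circ)
    r_rev = _count_unique(t, reverse_complement(r18rc), circ)
    # Each 18-mer must occur exactly once on the template, and the pair must
    # be convergent: forward on the top strand, reverse on the bottom.
    if len(f_fwd) + len(f_rev) != 1 or len(r_fwd) + len(r_rev) != 1:
        return None
    if not f_fwd or not r_fwd:
        return None
    fwd_3end = f_fwd[0] + k - 1
    rev_3end = r_fwd[0]
    return _product_from_positions(fwd, rev, template, fwd_3end, rev_3end)


def _mechanistic_pcr(
    fwd: Polynucleotide,
    rev: Polynucleotide,
    template: Polynucleotide,
    tm_threshold: float,
) -> str:
    products: set[str] = set()
    for a, b in ((fwd, rev), (rev, fwd)):
        plus = [s for s in find_anneal_sites(a, template, tm_threshold) if s.strand == "+"]
        minus = [s for s in find_anneal_sites(b, template, tm_threshold) if s.strand == "-"]
        for sa in plus:
            for sb in minus:
                p = _product_from_positions(a, b, template, sa.template_position, sb.template_position)
                if p is not None:
                    products.add(p if a is fwd else reverse_complement(p))
    if not products:
        raise NoProductError(
            f"No convergent annealing-site pair for {fwd.name or 'fwd'}/"
            f"{rev.name or 'rev'} on {template.name or 'template'}"
        )
    if len(products) > 1:
        raise AmbiguousProductError(
            f"{len(products)} distinct products possible for {fwd.name or 'fwd'}/"
            f"{rev.name or 'rev'} on {template.name or 'template'} "
            f"(multiple annealing sites or orientation problem)"
        )
    return products.pop()


def simulate_pcr(
    fwd: Polynucleotide,
    rev: Polynucleotide,
    template: Polynucleotide,
    product_name: str = "",
    expected_size: int | None = None,
    tm_threshold: float = DEFAULT_TM_THRESHOLD,
) -> Polynucleotide:
    """Predict the PCR product for two oligos on one template."""
    for oligo in (fwd, rev):
        if oligo.is_double_stranded and len(oligo.sequence) >= MAX_PRIMER_LENGTH:
            raise PCRError(f"{oligo.name or 'input'} is not usable as a primer")
    top = fast_pcr(fwd, rev, template)
    if top is None:
        top = fast_pcr(rev, fwd, template)
    if top is None:
        top = _mechanistic_pcr(fwd, rev, template, tm_threshold)
    if expected_size is not None and len(top) != expected_size:
        raise SizeMismatchError(
            f"PCR size check failed for {product_name or 'product'}: "
            f"expected {expected_size} bp, simulation gives {len(top)} bp"
        )
    return Polynucleotide(
        sequence=top,
        mod_ext5=fwd.mod_ext5 or Chem.HYDROXYL,
        mod_ext3=rev.mod_ext5 or Chem.HYDROXYL,
        name=product_name,
    )
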