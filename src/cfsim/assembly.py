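"""GoldenGate, Gibson, and Transform simulators.

GoldenGate is modelled as simultaneous type-IIS digestion and ligation: each
input is cut to completion, only fragments free of the recognition site can
participate (fragments that retain a site would be re-cut in the one-pot
reaction), and the participants must assemble into a single closed circle
with no recognition site left.  Because the real reaction runs cutting and
ligation simultaneously, the simulator takes a validating stance on overhang
design: with more than one participant, a fragment whose two ends are
mutually compatible would simply re-ligate, and a palindromic overhang can
anneal to itself — both are reported as errors rather than silently picking
one of the possible products.

Gibson joins linear DNAs wherever the maximal exact terminal overlap between
two fragment ends is at least 20 bp; shorter homology is invisible to the
detection window.  Transformation only verifies circularity, the single
physical requirement for propagating the DNA in a bacterial host.
"""

from __future__ import annotations

import logging

from .dna import Chem, Polynucleotide, find_sites, reverse_complement
from .digest import cut_all, simulate_ligate
from .enzymes import EnzymeTable, RestrictionEnzyme
from .errors import AssemblyError, LigationError, TransformError

log = logging.getLogger(__name__)

#: Exact terminal homology needed for a Gibson junction.
GIBSON_HOMOLOGY_LENGTH = 20


# ---------------------------------------------------------------------------
# GoldenGate
# ---------------------------------------------------------------------------

def _canonical_overhang(ext: str) -> str:
    rc = reverse_complement(ext)
    return min(ext, rc)


def simulate_goldengate(
    inputs: list[Polynucleotide],
    enzyme: RestrictionEnzyme,
    product_name: str = "",
) -> Polynucleotide:
    """Assemble *inputs* in a one-pot type-IIS cut/ligate reaction."""
    if not enzyme.is_type_iis:
        raise AssemblyError(
            f"GoldenGate needs a type IIS enzyme; {enzyme.name} cuts within "
            f"its recognition site"
        )
    participants: list[Polynucleotide] = []
    for dna in inputs:
        for frag in cut_all(dna, [enzyme]):
            if frag.is_circular:
                continue  # an uncut circle cannot enter the assembly
            if find_sites(enzyme.recognition, frag):
                continue  # still carries a site: would be re-cut in the pot
            participants.append(frag)
    if not participants:
        raise AssemblyError(
            f"No site-free fragments released by {enzyme.name}; nothing to assemble"
        )
    if len(participants) > 1:
        for frag in participants:
            if frag.ext5_kind == frag.ext3_kind and frag.ext5 == frag.ext3 and frag.ext5:
                raise AssemblyError(
                    f"Fragment {frag.name or '?'} carries the same overhang "
                    f"{frag.ext5} on both ends and will re-ligate on itself"
                )
        counts: dict[str, int] = {}
        for frag in participants:
            for ext in (frag.ext5, frag.ext3):
                if not ext:
                    raise AssemblyError(
                        f"Fragment {frag.name or '?'} has a blunt end; "
                        f"GoldenGate junctions need sticky overhangs"
                    )
                if ext == reverse_complement(ext):
                    raise AssemblyError(
                        f"Palindromic overhang {ext} can anneal to itself "
                        f"and re-ligate"
                    )
                key = _canonical_overhang(ext)
                counts[key] = counts.get(key, 0) + 1
        for key, c in counts.items():
            if c > 2:
                raise AssemblyError(
                    f"Overhang {key} occurs on {c} fragment ends; assembly is ambiguous"
                )
    try:
        product = simulate_ligate(participants, product_name=product_name)
    except LigationError as exc:
        raise AssemblyError(f"GoldenGate assembly failed: {exc}") from None
    if not product.is_circular:
        raise AssemblyError(
            f"GoldenGate product {product_name or '?'} did not close into a circle"
        )
    if find_sites(enzyme.recognition, product):
        raise AssemblyError(
            f"GoldenGate product {product_name or '?'} retains a {enzyme.name} "
            f"recognition site and would be re-cut"
        )
    return product


def simulate_goldengate_step(
    inputs: list[Polynucleotide],
    enzyme_name: str,
    table: EnzymeTable,
    product_name: str = "",
) -> Polynucleotide:
    return simulate_goldengate(inputs, table.lookup(enzyme_name), product_name)


# ---------------------------------------------------------------------------
# Gibson
# ---------------------------------------------------------------------------

def terminal_overlap(a: str, b: str, minimum: int = GIBSON_HOMOLOGY_LENGTH) -> int:
    """Longest k >= minimum with ``a[-k:] == b[:k]``; 0 when none exists."""
    for k in range(min(len(a), len(b)), minimum - 1, -1):
        if a[-k:] == b[:k]:
            return k
    return 0


def simulate_gibson(
    inputs: list[Polynucleotide],
    product_name: str = "",
    min_overlap: int = GIBSON_HOMOLOGY_LENGTH,
) -> Polynucleotide:
    """Join linear DNAs at exact >=20 bp terminal homologies.

    Fragments may enter in either orientation; every junction must be
    unambiguous.  A single fragment whose own ends share the homology closes
    into a circle; a chain that does not close is returned linear with a
    logged warning (in-vitro linear products are legitimate).
    """
    if not inputs:
        raise AssemblyError("Gibson needs at least one input")
    for dna in inputs:
        if dna.is_circular:
            raise AssemblyError(f"Gibson input {dna.name or '?'} must be linear")
        if not dna.is_double_stranded:
            raise AssemblyError(f"Gibson input {dna.name or '?'} must be double-stranded")
    strands = [d.top_strand for d in inputs]
    names = [inp.name or f"fragment{i}" for i, inp in enumerate(inputs)]

    while len(strands) > 1:
        junction = None
        for i, s in enumerate(strands):
            right: list[tuple[int, str]] = []
            left: list[tuple[int, str]] = []
            for j, u in enumerate(strands):
                if i == j:
                    continue
                for orient, v in (("+", u), ("-", reverse_complement(u))):
                    if terminal_overlap(s, v, min_overlap):
                        right.append((j, orient))
                    if terminal_overlap(v, s, min_overlap):
                        left.append((j, orient))
            if len(right) > 1 or len(left) > 1:
                end = "right" if len(right) > 1 else "left"
                raise AssemblyError(
                    f"Gibson junction at the {end} end of {names[i]} is ambiguous: "
                    f"{max(len(right), len(left))} partner ends share >= "
                    f"{min_overlap} bp homology"
                )
            if right and junction is None:
                j, orient = right[0]
                junction = (i, j, orient)
        if junction is None:
            raise AssemblyError(
                f"Gibson cannot join the remaining {len(strands)} fragment(s): "
                f"no end pair shares >= {min_overlap} bp of terminal homology "
                f"({', '.join(names)})"
            )
        i, j, orient = junction
        v = strands[j] if orient == "+" else reverse_complement(strands[j])
        k = terminal_overlap(strands[i], v, min_overlap)
        merged = strands[i] + v[k:]
        merged_name = f"{names[i]}~{names[j]}"
        strands = [s for idx, s in enumerate(strands) if idx not in (i, j)] + [merged]
        names = [nm for idx, nm in enumerate(names) if idx not in (i, j)] + [merged_name]

    final = strands[0]
    # Self-overlap must stop short of the whole molecule.
    k = 0
    for cand in range(len(final) - 1, min_overlap - 1, -1):
        if final[-cand:] == final[:cand]:
            k = cand
            break
    if k:
        return Polynucleotide.plasmid(final[:-k], name=product_name)
    log.warning(
        "Gibson product %s did not circularise; returning a linear DNA",
        product_name or "?",
    )
    return Polynucleotide(
        sequence=final,
        mod_ext5=Chem.HYDROXYL,
        mod_ext3=Chem.HYDROXYL,
        name=product_name,
    )


# ---------------------------------------------------------------------------
# Transform
# ---------------------------------------------------------------------------

def simulate_transform(
    dna: Polynucleotide,
    host: str,
    product_name: str = "",
    antibiotic: str | None = None,
    temperature: float | None = None,
) -> Polynucleotide:
    """Verify the DNA can propagate in a host: it must be circular.

    The DNA is returned unchanged under the strain (product) name; host,
    antibiotic and incubation temperature are recorded in the event log only.
    """
    if not dna.is_circular:
        raise TransformError(
            f"Cannot transform {host} with {dna.name or 'DNA'}: the DNA is "
            f"linear, and propagation in a bacterial host requires a circle"
        )
    details = [f"host={host}"]
    if antibiotic:
        details.append(f"antibiotic={antibiotic}")
    if temperature is not None:
        details.append(f"temperature={temperature:g} degC")
    log.info("Transform %s -> %s (%s)", dna.name or "DNA", product_name, ", ".join(details))
    return dna.renamed(product_name)
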