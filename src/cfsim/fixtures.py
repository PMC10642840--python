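"""Deterministic synthetic substrates for exercising every simulator path.

All generators draw from a single seeded ``random.Random`` instance per
call: the same parameters and seed always reproduce the same molecules, so
golden outputs never drift.  Substrates can also be written out as a
complete Experiment folder (CF shorthand + oligo TSV + GenBank plasmid) for
end-to-end runs.
"""

from __future__ import annotations

import random
from pathlib import Path

from .dna import Polynucleotide, find_sites, reverse_complement
from .enzymes import RestrictionEnzyme
from .errors import FixtureError

_BASES = "ACGT"
_MAX_TRIES = 500


def make_random_dna(
    length: int,
    seed: int,
    required_sites: list[tuple[str, int]] | None = None,
    forbidden_patterns: list[str] | None = None,
    circular: bool = False,
    name: str = "",
) -> Polynucleotide:
    """Uniform random DNA with planted motifs and excluded patterns.

    Each ``(pattern, position)`` in *required_sites* is planted verbatim at
    its top-strand position and must end up occurring nowhere else on either
    strand; *forbidden_patterns* must be absent from both strands.  Bounded
    rejection sampling raises :class:`FixtureError` if the constraints are
    not satisfiable.
    """
    required = list(required_sites or [])
    forbidden = list(forbidden_patterns or [])
    for pattern, position in required:
        if position < 0 or position + len(pattern) > length:
            raise FixtureError(
                f"Required site {pattern} at {position} does not fit in {length} bp"
            )
    spans = sorted((pos, pos + len(pat)) for pat, pos in required)
    for (_, end_a), (start_b, _) in zip(spans, spans[1:]):
        if start_b < end_a:
            raise FixtureError("Required sites overlap")
    rng = random.Random(seed)
    for _ in range(_MAX_TRIES):
        seq = list(rng.choices(_BASES, k=length))
        for pattern, position in required:
            seq[position : position + len(pattern)] = pattern.upper()
        candidate = "".join(seq)
        probe = Polynucleotide.plasmid(candidate) if circular else Polynucleotide.blunt_dsdna(candidate)
        ok = True
        for pattern, position in required:
            hits = {pos for pos, _ in find_sites(pattern, probe)}
            if hits != {position}:
                ok = False
                break
        if ok:
            for pattern in forbidden:
                if find_sites(pattern, probe):
                    ok = False
                    break
        if ok:
            if circular:
                return Polynucleotide.plasmid(candidate, name=name)
            return Polynucleotide.blunt_dsdna(candidate, name=name)
    raise FixtureError(
        f"Could not generate {length} bp DNA satisfying constraints after "
        f"{_MAX_TRIES} tries (seed {seed})"
    )


def make_primer_pair(
    template: Polynucleotide,
    span: tuple[int, int],
    anneal_len: int = 20,
    fwd_tail: str = "",
    rev_tail: str = "",
    phosphorylated: bool = False,
    fwd_name: str = "fwd",
    rev_name: str = "rev",
) -> tuple[Polynucleotide, Polynucleotide]:
    """Primers amplifying ``template[start:end]`` (mod length for circles).

    The forward oligo is ``fwd_tail`` + the first *anneal_len* bases of the
    span; the reverse oligo is ``rev_tail`` + the reverse complement of the
    span's last *anneal_len* bases.
    """
    if anneal_len < 6:
        raise FixtureError(f"anneal_len {anneal_len} is too short to prime (< 6)")
    start, end = span
    seq = template.sequence
    n = len(seq)
    if template.is_circular:
        doubled = seq + seq
        start %= n
        stop = end % n
        if stop <= start:
            stop += n
        region = doubled[start:stop]
    else:
        if not (0 <= start < end <= n):
            raise FixtureError(f"Span {span} outside template of {n} bp")
        region = seq[start:end]
    if len(region) < 2 * anneal_len:
        raise FixtureError("Span too short for non-overlapping primers")
    fwd = Polynucleotide.oligo(fwd_tail + region[:anneal_len], name=fwd_name,
                               phosphorylated=phosphorylated)
    rev = Polynucleotide.oligo(rev_tail + reverse_complement(region[-anneal_len:]),
                               name=rev_name, phosphorylated=phosphorylated)
    return fwd, rev


def make_goldengate_parts(
    n_parts: int,
    enzyme: RestrictionEnzyme,
    overhang_plan: list[str],
    seed: int,
    core_length: int = 60,
    trap: bool = False,
) -> tuple[list[Polynucleotide], Polynucleotide]:
    """Linear parts whose type-IIS digestion releases a planned ring of
    payload fragments, plus the expected circular product.

    ``overhang_plan[i]`` is the junction overhang between part ``i-1`` and
    part ``i`` (so part i is released with ``ext5 = plan[i]`` and
    ``ext3 = plan[(i+1) % n]``).  With ``trap=True`` the last junction
    reuses the first overhang, reproducing the classic mis-design in which
    one fragment carries the same overhang on both ends and re-ligates.
    """
    if not enzyme.is_type_iis:
        raise FixtureError(f"{enzyme.name} is not a type IIS enzyme")
    if len(overhang_plan) != n_parts:
        raise FixtureError("overhang_plan must have one overhang per part")
    plan = [o.upper() for o in overhang_plan]
    if trap:
        if n_parts < 2:
            raise FixtureError("The re-ligation trap needs at least two parts")
        plan[0] = plan[-1] if n_parts > 1 else plan[0]
    else:
        if len(set(plan)) != len(plan):
            raise FixtureError("Duplicate overhangs in plan (use trap=True on purpose)")
        for ov in plan:
            if ov == reverse_complement(ov):
                raise FixtureError(f"Palindromic overhang {ov} cannot be used")
    # Bases between the recognition site and the overhang it releases.
    lead = enzyme.cut_top - len(enzyme.recognition)
    if lead < 0 or enzyme.cut_bottom < enzyme.cut_top:
        raise FixtureError(f"{enzyme.name} geometry unsupported by this builder")
    if enzyme.overhang_length != len(plan[0]) or any(len(o) != len(plan[0]) for o in plan):
        raise FixtureError(
            f"Overhangs must all be {enzyme.overhang_length} nt for {enzyme.name}"
        )
    rng = random.Random(seed)
    site = enzyme.recognition
    rc_site = reverse_complement(site)
    parts: list[Polynucleotide] = []
    cores: list[str] = []
    for i in range(n_parts):
        for _ in range(_MAX_TRIES):
            core = "".join(rng.choices(_BASES, k=core_length))
            flank_l = "".join(rng.choices(_BASES, k=6))
            flank_r = "".join(rng.choices(_BASES, k=6))
            lead_l = "".join(rng.choices(_BASES, k=lead))
            lead_r = "".join(rng.choices(_BASES, k=lead))
            top = (
                flank_l + site + lead_l + plan[i] + core
                + plan[(i + 1) % n_parts] + lead_r + rc_site + flank_r
            )
            probe = Polynucleotide.blunt_dsdna(top)
            if len(find_sites(site, probe)) == 2:  # exactly the two planted sites
                parts.append(probe.renamed(f"part{i}"))
                cores.append(core)
                break
        else:
            raise FixtureError(f"Could not build part {i} free of extra sites")
    expected_seq = "".join(plan[i] + cores[i] for i in range(n_parts))
    expected = Polynucleotide.plasmid(expected_seq, name="expected")
    return parts, expected


def write_experiment_folder(folder: "str | Path", cfs: dict[str, str],
                            oligos: dict[str, str] | None = None,
                            plasmids: dict[str, Polynucleotide] | None = None) -> Path:
    """Materialise shorthand texts, an oligo TSV, and GenBank plasmids as an
    Experiment folder; returns the folder path."""
    from .experiment import _genbank_record  # late import to avoid a cycle
    from Bio import SeqIO

    path = Path(folder)
    path.mkdir(parents=True, exist_ok=True)
    for name, text in cfs.items():
        (path / f"{name}.txt").write_text(text)
    if oligos:
        lines = ["name\tsequence"] + [f"{n}\t{s}" for n, s in oligos.items()]
        (path / "oligos.tsv").write_text("\n".join(lines) + "\n")
    for name, poly in (plasmids or {}).items():
        with (path / f"{name}.gb").open("w") as fh:
            SeqIO.write([_genbank_record(name, poly)], fh, "genbank")
    return path
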