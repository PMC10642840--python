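# Methods and design notes

## The Polynucleotide model

A DNA species is represented by the coding (top) strand of its fully
duplexed region plus two overhangs, each a coding-sense string with a
protrusion kind (`five_prime`, `three_prime`, `blunt`), the chemistry of
the two 5' termini (`hydroxyl` or `phosphate`; the left field refers to the
top strand, the right field to the bottom strand), a strandedness flag and
a circularity flag. Invariants enforced on construction: sequences are
IUPAC DNA, uppercase-normalised; a blunt kind is equivalent to an empty
overhang string; circular molecules carry no overhangs and no end
chemistry; single strands carry no overhangs at all. In JSON, a 3'
protrusion is serialised as a `-` prefix on the extension string; the
normative dialect is `src/cfsim/data/cf_schema.json`.

Because both ends of one restriction cut carry the *same* overhang string
in coding-strand sense, sticky-end compatibility reduces to string equality
plus matching protrusion kind. Rotation- and flip-aware equality
(`equivalent`) is used whenever circular products are compared.

Coordinates are 0-based, half-open, top-strand throughout. The length of a
linear molecule counts each overhang once (`ext5 + sequence + ext3`).

Structure inference for bare name/sequence pairs: an explicit kind keyword
(`oligo`, `dsDNA`, `plasmid`) wins; otherwise sequences shorter than 100
bases become single-stranded 5'-hydroxyl oligos and sequences of 100 bases
or more become blunt double-stranded DNAs. The exact boundary value 100 is
assigned to dsDNA so the rule is total and testable.

## Digestion

A concrete cut event is the pair of strand scissions `(top_cut,
bottom_cut)` in parent coordinates; the interval between them becomes the
shared overhang, 5'-protruding when the top cut is left of the bottom cut,
3'-protruding when right of it. Minus-strand recognition sites map their
offsets from the right edge of the match window. Degenerate recognition
patterns (IUPAC set-intersection matching, so pattern N matches target N)
cut at fixed offsets within each concrete match. All cut positions are
computed on the intact parent and applied at once — digestion means "cut
to completion"; partial digests are out of scope by decision. Type-IIS
cuts whose scissile bond falls off the end of a linear substrate are
skipped. Fresh 5' termini are phosphorylated; the parent's outer ends keep
their chemistry.

Fragment indexing is 0-based. Linear parents number fragments left to
right; circular parents start numbering at the first (lowest-position) cut
of the first enzyme named in the step, which is the reference point the
`fragSelect` parameter is defined against. Every digest logs each
fragment's index and size so a wrong `fragSelect` is easy to diagnose.

## Ligation

A junction requires identical overhang strings with the same protrusion
kind (or two blunt ends) *and* a phosphate on both 5' termini being sealed
— a dephosphorylated end blocks the junction entirely (nicked products are
not modelled). Fragments may enter in either orientation. Before every
join the simulator verifies that no end has more than one possible partner
end; otherwise more than one distinct assembly is chemically possible and
the step fails with an ambiguity error rather than guessing. A final
single fragment whose own ends are joinable circularises, absorbing the
overhang into the circle once (circle length = duplex + one overhang).

## PCR

The fast path fires only for one template and two oligos whose 3'-terminal
18-mers each occur exactly once on the template, on opposite strands, in
convergent orientation; the product is then the forward oligo verbatim
(tails included), the intervening template, and the reverse complement of
the reverse oligo. Otherwise the mechanistic path enumerates annealing
sites: every exact match of the oligo's 3'-terminal hexamer seeds an
ungapped 3'-anchored alignment, and a site is kept when the estimated
melting temperature of the annealed duplex clears the threshold. All
convergent site pairs are turned into candidate products; zero candidates
is a no-product error, more than one distinct candidate an ambiguity
error. Circular templates are searched across the origin, which is what
makes inverse PCR work.

Tm model: the GC-corrected Wallace-type estimate
`Tm = 64.9 + 41·(nGC − 16.4)/N` over the annealed window, minus 5 °C per
mismatched position, with an acceptance threshold of 45 °C (configurable
per call). The model is deliberately coarse — it exists to discriminate
plausible priming sites from seed-only hits, not to predict reaction
conditions. One consistency rule is layered on top: a perfect 3'-terminal
match at least as long as the fast-path criterion (18 bp) is always
accepted, whatever its base composition, so the mechanistic path strictly
subsumes the fast path and the two can never disagree on a substrate both
handle. Product 5' ends inherit each priming oligo's 5' chemistry, so
phosphorylated primers yield ligatable amplicons.

## GoldenGate

Modelled as simultaneous cutting and ligation: each input is digested to
completion with the (required type-IIS) enzyme, and only released
fragments free of the recognition site participate — a fragment still
carrying a site would be re-cut in the pot. With more than one
participant the overhang design is validated before assembly: a fragment
with the same overhang on both ends would re-ligate on itself; a
palindromic overhang can anneal to itself; an overhang class (counted up
to reverse complement) present on more than two ends makes the assembly
ambiguous. All three are errors. A single released fragment may
re-circularise, which is the legitimate one-part use. The assembled
product must be a closed circle and is re-checked to be free of the
recognition site.

## Gibson

A junction exists wherever the maximal exact terminal overlap between one
fragment's end and another's start (in either orientation) is at least
20 bp; longer shared ends are found because their terminal 20-mer is part
of the longer exact overlap, and 19 bp is invisible by design. Homology is
only detected at fragment termini, not internally. Junction ambiguity
(an end with two possible partners) is an error. A chain that closes on
itself returns a circle; an open chain is returned linear with a logged
warning, since linear in-vitro assemblies are legitimate products.

## Experiments

A folder is parsed into construction files (`.txt`), sequence tables
(`.tsv`, header optional, extra columns ignored — the layout of an oligo
order form), and GenBank records (`.gb`, `.seq`, `.str`, `.ape`; topology
read from the LOCUS line). The same name appearing twice with the same
sequence is deduplicated; with different sequences it is a hard conflict
naming both files — catching that clerical error is the feature's reason
to exist.

Each construction file exports exactly one product: the product of its
last step. Step-level intermediates are file-local, so reused scratch
names like `pcrpdt` cannot collide across files. Execution order is a
topological sort of the final-product dependency graph, with independent
files ordered lexicographically by product name so runs are reproducible;
cycles and duplicate final products are errors. A failing file is
recorded and independent files still run; files consuming the failed
product are skipped with a reason.

Outputs: one minimal GenBank record per final product (LOCUS with length,
`ds-DNA`, topology; 60-column ORIGIN; no feature table — round-trippable
by mainstream parsers), `C5seqs.txt` as TSV of name, classification and
sequence for inputs, intermediates (qualified as `file:name`) and
products, and `C5log.txt` with every event. Log timestamps use a fixed
format and can be disabled (`--no-timestamps`) for golden-file
comparisons; with them disabled, repeated runs are bit-identical.

## Synthetic substrates

The fixture generators stand in for a library of real plasmid maps. They
produce uniform random ACGT backgrounds from a single seeded generator per
call, with recognition sites planted at exact positions (verified unique
on both strands) and unwanted patterns excluded by bounded rejection
sampling; primer pairs are cut from a template span with optional tails;
Golden Gate part sets are built around a junction-overhang plan with the
expected product computed by construction, including a `trap` variant that
duplicates an overhang to reproduce the classic re-ligation mis-design.
What they do not emulate: repeat structure, biased composition, methylation
and real vector features (origins, markers). Passing tests therefore show
the chemistry and bookkeeping are right on clean substrates, not that any
particular natural plasmid will behave.

Test and probe problem sizes — 300–600 bp substrates, 200 random plasmids
for the digestion/ligation round trip, 100 cases for the PCR path
agreement — were chosen as the smallest sizes at which every code path
(unique primer sites, three distinct junctions, origin-spanning features)
is exercised with comfortable margin.

## Known limitations

No partial digests, nicked products, blunting/phosphatase operations, PCA/
SOEing/Klenow, RNA or mixed structures, methylation sensitivity, or
host-biology checks in Transform beyond circularity. The shorthand dialect
choices not fixed by the format's published description (comment markers
`#` and `//`; comma- or space-separated enzyme lists, emitted
comma-separated; Transform token order `dna host [antibiotic]
[temperature] product`) are documented here and enforced consistently.
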