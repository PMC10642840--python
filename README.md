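# cfsim — Construction File parsing, validation, and in-silico cloning

`cfsim` is a validating simulator for recombinant-DNA construction plans
written as **Construction Files (CF)**: minimal, ordered descriptions of a
cloning experiment as operations over named sequences. A CF can be written
in a human-readable TSV **shorthand** (one step per line, ending with the
product name) or as a detailed **JSON** document, and `cfsim` parses both,
interconverts them losslessly, and simulates the chemistry step by step:

* **PCR** — fast exact prediction when both primers match the template
  perfectly over their 3'-terminal 18 bp, with a mechanistic
  annealing-and-extension fallback (3' hexamer seed + melting-temperature
  filter) for mutagenic or otherwise imperfect primers.
* **Digest** — REBASE-driven restriction digestion to completion, with
  degenerate recognition sites, 5' and 3' overhangs, fresh 5' phosphates on
  cut ends, and `fragSelect` indexing of fragments.
* **Ligate** — sticky-end ligation requiring matching overhangs and 5'
  phosphates at every junction; self-compatible molecules circularise.
* **GoldenGate** — one-pot type-IIS assembly with validation of overhang
  design (re-ligation traps, palindromic or over-used overhangs, retained
  recognition sites are all reported as errors).
* **Gibson** — joining of linear DNAs at exact terminal homologies of at
  least 20 bp, orientation- and order-independent.
* **Transform** — circularity check and strain naming.

The physical state of every molecule is tracked as a `Polynucleotide`: the
duplexed region as the top strand, the two overhangs with their protrusion
kind (5'/3'/blunt), the 5'-end chemistry of both strands
(hydroxyl/phosphate), strandedness, and circularity. This is exactly the
level of detail a bench scientist uses to reason about whether a ligation
will work — and it is what lets the simulator catch dephosphorylated ends,
incompatible sticky ends, and ambiguous assemblies before reagents are
wasted.

Beyond single files, an **Experiment folder** (CF `.txt` files plus
sequence tables in `.tsv` and GenBank records in `.gb/.seq/.str/.ape`) can
be simulated as a unit: `cfsim` orders the files by their product
dependencies, runs them, writes one GenBank file per product, and emits
`C5seqs.txt` (all sequences) and `C5log.txt` (all events).

## Worked example

A classic four-step clone — amplify an insert with tailed primers, cut
insert and vector with EcoRI + BamHI, ligate, transform:

```text
fwdD	AAGAATTCCGGGTGCCCTTATTTGTAAT
revD	AAGGATCCACCCTCCTCAAGTGGGCCGC
plasmid	pDonor	<400 bp sequence>
plasmid	pVector	<300 bp sequence>
PCR	fwdD	revD	pDonor	pcrpdt
Digest	pcrpdt	EcoRI,BamHI	1	insertFrag
Digest	pVector	EcoRI,BamHI	1	bbFrag
Ligate	insertFrag	bbFrag	pFinal
Transform	pFinal	Mach1	Amp	strainFinal
```

```console
$ cfsim validate demo_cf.txt
Digest of pcrpdt with EcoRI+BamHI yields 3 fragment(s): [0] 7 bp, [1] 210 bp, [2] 7 bp
Digest of pVector with EcoRI+BamHI yields 2 fragment(s): [0] 104 bp, [1] 204 bp
Transform pFinal -> strainFinal (host=Mach1, antibiotic=Amp)
PASS	step 0: PCR fwdD revD pDonor -> pcrpdt (linear dsDNA, 216 bp)
PASS	step 1: Digest pcrpdt -> insertFrag (linear dsDNA, 210 bp)
PASS	step 2: Digest pVector -> bbFrag (linear dsDNA, 204 bp)
PASS	step 3: Ligate insertFrag bbFrag -> pFinal (circular dsDNA, 406 bp)
PASS	step 4: Transform pFinal -> strainFinal (circular dsDNA, 406 bp)
```

Reading the numbers: the PCR product is the 200 bp amplified span plus two
8 bp enzyme tails (216 bp); each digest logs its fragment sizes so the
`fragSelect` index can be checked at a glance (fragment 1 is the central
210 bp insert and the 204 bp vector backbone); the ligation closes a
406 bp circle (210 + 204 − 4 − 4 bp of shared overhangs counted once), and
transformation succeeds because the product is circular. `cfsim simulate`
prints the final product's sequence; `cfsim convert --to json` /
`--to shorthand` interconvert formats; `cfsim run-experiment FOLDER` runs a
whole folder.

Had the design been wrong — a dephosphorylated junction, a Golden Gate
part with the same overhang on both ends, a primer that anneals twice —
simulation stops at that step with a message describing the problem, which
is the point of the tool.

## Layout

```
src/cfsim/
  dna.py         Polynucleotide model, reverse complement, IUPAC site finding
  formats.py     CF shorthand + JSON parsing/serialisation, structure inference
  enzymes.py     REBASE-style enzyme table (bundled: src/cfsim/data/enzymes.tsv)
  pcr.py         fast-path and mechanistic PCR
  digest.py      cut-to-completion digestion, sticky-end ligation
  assembly.py    GoldenGate, Gibson, Transform
  experiment.py  CF execution, folder discovery, dependency ordering, outputs
  fixtures.py    seeded generators for synthetic substrates
  cli.py         the `cfsim` command
docs/methods.md  model assumptions, parameters, and design notes
```
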