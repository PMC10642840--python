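"""Execute Construction Files and whole Experiment folders.

A Construction File is simulated step by step; each step's product is
registered under its name before the next step runs, and any failure
terminates the file with a message naming the step.  An Experiment is a
folder of CFs (``.txt``), oligo/sequence tables (``.tsv``) and GenBank
records (``.gb``, ``.seq``, ``.str``, ``.ape``); CFs are executed in
dependency order (a file consuming another file's final product runs after
it), products are written as GenBank files, and two logs record all
sequences (``C5seqs.txt``) and all events (``C5log.txt``).

Intermediate step products are scoped to their own CF: only a file's final
product is exported to the shared registry, so name reuse across files
(every file calling its amplicon ``pcrpdt``) stays harmless.
"""

from __future__ import annotations

import datetime
import heapq
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assembly import simulate_gibson, simulate_goldengate_step, simulate_transform
from .digest import simulate_digest, simulate_ligate
from .dna import Polynucleotide
from .enzymes import EnzymeTable, default_table
from .errors import (
    CFError,
    CycleError,
    ExperimentError,
    MissingSequenceError,
    NameCollisionError,
    ParseError,
)
from .formats import ConstructionFile, Step, infer_polynucleotide, parse_shorthand
from .pcr import simulate_pcr

log = logging.getLogger(__name__)

GENBANK_SUFFIXES = {".gb", ".seq", ".str", ".ape"}


def simulate_step(step: Step, registry: dict[str, Polynucleotide], table: EnzymeTable) -> Polynucleotide:
    """Dispatch one step to its simulator, resolving input names."""
    def resolve(name: str) -> Polynucleotide:
        if name not in registry:
            raise MissingSequenceError(
                f"{step.operation} step needs sequence {name!r}, which is not defined"
            )
        return registry[name]

    inputs = [resolve(name) for name in step.inputs]
    if step.operation == "PCR":
        return simulate_pcr(
            inputs[0], inputs[1], inputs[2],
            product_name=step.product,
            expected_size=step.params.get("product_size"),
        )
    if step.operation == "Digest":
        return simulate_digest(
            inputs[0], step.params["enzymes"], step.params["fragSelect"],
            table, product_name=step.product,
        )
    if step.operation == "Ligate":
        return simulate_ligate(inputs, product_name=step.product)
    if step.operation == "GoldenGate":
        return simulate_goldengate_step(
            inputs, step.params["enzyme"], table, product_name=step.product
        )
    if step.operation == "Gibson":
        return simulate_gibson(inputs, product_name=step.product)
    if step.operation == "Transform":
        return simulate_transform(
            inputs[0], step.params["host"],
            product_name=step.product,
            antibiotic=step.params.get("antibiotic"),
            temperature=step.params.get("temperature"),
        )
    raise CFError(f"No simulator for operation {step.operation}")  # pragma: no cover


def simulate_construction_file(
    cf: ConstructionFile,
    registry: dict[str, Polynucleotide] | None = None,
    table: EnzymeTable | None = None,
) -> tuple[dict[str, Polynucleotide], list[str]]:
    """Run every step of *cf* in order.

    Returns the mapping of step-product names to molecules (all of them, so
    intermediates are inspectable) and the event log.  On any step failure a
    :class:`CFError` is raised carrying the step index and operation; no
    partial products are returned.
    """
    table = table or default_table()
    local: dict[str, Polynucleotide] = {}
    local.update(registry or {})
    for name, poly in cf.sequences.items():
        local[name] = poly
    events: list[str] = []
    products: dict[str, Polynucleotide] = {}
    for index, step in enumerate(cf.steps):
        try:
            product = simulate_step(step, local, table)
        except CFError as exc:
            raise type(exc)(
                f"{cf.name or 'CF'} step {index} ({step.operation} -> "
                f"{step.product}): {exc}"
            ) from exc
        local[step.product] = product
        products[step.product] = product
        events.append(
                f"step {index}: {step.operation} "
                f"{' '.join(step.inputs)} -> {step.product} "
                f"({_classify(product)}, {len(product)} bp)"
        )
    return products, events


def _classify(p: Polynucleotide) -> str:
    shape = "circular" if p.is_circular else "linear"
    strands = "ds" if p.is_double_stranded else "ss"
    return f"{shape} {strands}DNA"


# ---------------------------------------------------------------------------
# Experiment folders
# ---------------------------------------------------------------------------

@dataclass
class Experiment:
    construction_files: list[ConstructionFile] = field(default_factory=list)
    sequence_registry: dict[str, Polynucleotide] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    #: remembers which file defined each registry entry, for conflict messages
    provenance: dict[str, str] = field(default_factory=dict)


def _parse_tsv_sequences(text: str, source: str, exp: Experiment) -> None:
    """``name<TAB>sequence[<TAB>extra...]`` rows; a header row is tolerated;
    extra columns (scale, purification, ...) are preserved in spirit but
    ignored."""
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split("\t") if p.strip()] or line.split()
        if len(parts) < 2:
            raise ParseError(f"{source}:{lineno}: expected 'name<TAB>sequence'")
        name, seq = parts[0], parts[1]
        try:
            poly = infer_polynucleotide(name, seq)
        except CFError:
            if lineno == 1:
                continue  # header row
            raise
        _register(exp, name, poly, source)


def _register(exp: Experiment, name: str, poly: Polynucleotide, source: str) -> None:
    if name in exp.sequence_registry:
        existing = exp.sequence_registry[name]
        if existing.sequence == poly.sequence:
            return  # same molecule twice is fine: deduplicate
        raise NameCollisionError(
            f"Sequence name {name!r} is defined with different sequences in "
            f"{exp.provenance[name]} and {source}"
        )
    exp.sequence_registry[name] = poly
    exp.provenance[name] = source


def _parse_genbank(path: Path, exp: Experiment) -> None:
    for record in SeqIO.parse(str(path), "genbank"):
        circular = record.annotations.get("topology", "linear") == "circular"
        name = record.name if record.name not in ("", ".") else path.stem
        seq = str(record.seq)
        poly = (
            Polynucleotide.plasmid(seq, name=name)
            if circular
            else Polynucleotide.blunt_dsdna(seq, name=name)
        )
        _register(exp, name, poly, path.name)


def parse_experiment_folder(path: "str | Path") -> Experiment:
    """Discover CFs and sequence records in a folder."""
    folder = Path(path)
    if not folder.is_dir():
        raise ExperimentError(f"{folder} is not a readable folder")
    exp = Experiment()
    for entry in sorted(folder.iterdir()):
        if entry.is_dir():
            continue
        suffix = entry.suffix.lower()
        try:
            if suffix == ".txt":
                cf = parse_shorthand(entry.read_text(), name=entry.stem)
                if cf.steps:
                    exp.construction_files.append(cf)
                else:
                    for name, poly in cf.sequences.items():
                        _register(exp, name, poly, entry.name)
            elif suffix == ".tsv":
                _parse_tsv_sequences(entry.read_text(), entry.name, exp)
            elif suffix in GENBANK_SUFFIXES:
                _parse_genbank(entry, exp)
        except NameCollisionError:
            raise
        except CFError as exc:
            exp.warnings.append(f"Skipped {entry.name}: {exc}")
            log.warning("Skipped %s: %s", entry.name, exc)
    return exp


def order_construction_files(exp: Experiment) -> list[ConstructionFile]:
    """Topological execution order over final-product dependencies.

    CF B runs after CF A when B consumes A's final product.  Independent
    files are ordered lexicographically by final product name so runs are
    reproducible.
    """
    cfs = exp.construction_files
    by_product: dict[str, int] = {}
    for i, cf in enumerate(cfs):
        if not cf.final_product:
            continue
        if cf.final_product in by_product:
            other = cfs[by_product[cf.final_product]]
            raise NameCollisionError(
                f"Construction files {other.name!r} and {cf.name!r} both "
                f"export the final product {cf.final_product!r}"
            )
        by_product[cf.final_product] = i
    deps: dict[int, set[int]] = {i: set() for i in range(len(cfs))}
    dependents: dict[int, set[int]] = {i: set() for i in range(len(cfs))}
    for i, cf in enumerate(cfs):
        for name in cf.external_inputs():
            j = by_product.get(name)
            if j is not None and j != i:
                deps[i].add(j)
                dependents[j].add(i)
    ready = [
        (cfs[i].final_product, i) for i in range(len(cfs)) if not deps[i]
    ]
    heapq.heapify(ready)
    order: list[int] = []
    remaining = {i: set(d) for i, d in deps.items()}
    while ready:
        _, i = heapq.heappop(ready)
        order.append(i)
        for j in dependents[i]:
            remaining[j].discard(i)
            if not remaining[j] and j not in order:
                heapq.heappush(ready, (cfs[j].final_product, j))
    if len(order) != len(cfs):
        cycled = sorted(cfs[i].name or cfs[i].final_product for i in range(len(cfs)) if i not in order)
        raise CycleError(f"Dependency cycle among construction files: {', '.join(cycled)}")
    return [cfs[i] for i in order]


@dataclass
class ExperimentReport:
    succeeded: list[str] = field(default_factory=list)
    failed: dict[str, str] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)
    products: dict[str, Polynucleotide] = field(default_factory=dict)


def _genbank_record(name: str, poly: Polynucleotide) -> SeqRecord:
    record = SeqRecord(Seq(poly.top_strand), id=name[:16] or "product", name=name[:16] or "product")
    record.annotations["molecule_type"] = "ds-DNA" if poly.is_double_stranded else "ss-DNA"
    record.annotations["topology"] = "circular" if poly.is_circular else "linear"
    record.description = _classify(poly)
    return record


def simulate_experiment(
    exp: Experiment,
    output_dir: "str | Path",
    table: EnzymeTable | None = None,
    timestamps: bool = True,
) -> ExperimentReport:
    """Simulate every CF in dependency order and write products and logs.

    Outputs in *output_dir*: one ``<product>.gb`` per CF final product,
    ``C5seqs.txt`` (TSV of name, kind, sequence for all inputs,
    intermediates, and products) and ``C5log.txt`` (the event log).  A CF
    failure is recorded and independent files still run; files that depend
    on the failed product are skipped with a reason.
    """
    table = table or default_table()
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    ordered = order_construction_files(exp)
    report = ExperimentReport()
    registry = dict(exp.sequence_registry)
    log_lines: list[str] = []

    def event(message: str) -> None:
        if timestamps:
            stamp = datetime.datetime.now().strftime("%Y-%m-%d %H:%M:%S")
            log_lines.append(f"[{stamp}] {message}")
        else:
            log_lines.append(message)
        log.info("%s", message)

    for warning in exp.warnings:
        event(f"WARNING {warning}")

    seq_rows: list[tuple[str, str, str]] = []
    for name, poly in sorted(exp.sequence_registry.items()):
        seq_rows.append((name, _classify(poly) + " input", poly.top_strand))

    unavailable: dict[str, str] = {}  # final product -> reason
    for cf in ordered:
        label = cf.name or cf.final_product
        missing = [
            name for name in sorted(cf.external_inputs())
            if name not in registry and name in unavailable
        ]
        if missing:
            reason = f"skipped: upstream failure ({', '.join(missing)})"
            report.skipped[label] = reason
            unavailable[cf.final_product] = label
            event(f"SKIP {label}: {reason}")
            continue
        event(f"BEGIN {label}")
        try:
            products, events = simulate_construction_file(cf, registry, table)
        except CFError as exc:
            report.failed[label] = str(exc)
            unavailable[cf.final_product] = label
            event(f"FAIL {label}: {exc}")
            continue
        for line in events:
            event(f"  {label}: {line}")
        for name, poly in products.items():
            kind = "product" if name == cf.final_product else "intermediate"
            key = name if name == cf.final_product else f"{label}:{name}"
            seq_rows.append((key, _classify(poly) + " " + kind, poly.top_strand))
        final = products[cf.final_product]
        registry[cf.final_product] = final
        report.products[cf.final_product] = final
        report.succeeded.append(label)
        event(f"END {label}: {cf.final_product} ({_classify(final)}, {len(final)} bp)")

    for name, poly in report.products.items():
        handle = io.StringIO()
        SeqIO.write([_genbank_record(name, poly)], handle, "genbank")
        (outdir / f"{name}.gb").write_text(handle.getvalue())

    seqs_path = outdir / "C5seqs.txt"
    with seqs_path.open("w") as fh:
        fh.write("name\tkind\tsequence\n")
        seen = set()
        for name, kind, seq in seq_rows:
            if name in seen:
                continue
            seen.add(name)
            fh.write(f"{name}\t{kind}\t{seq}\n")
    (outdir / "C5log.txt").write_text("\n".join(log_lines) + ("\n" if log_lines else ""))
    return report
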