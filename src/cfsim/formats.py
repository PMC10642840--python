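"""Construction File formats: shorthand text and JSON.

A Construction File (CF) is an ordered list of cloning steps plus local
name -> sequence definitions.  Two serialisations are supported:

* **Shorthand** — one step per line, whitespace (preferably tab) separated,
  starting with an operation keyword and ending with the product name.
  Lines with exactly two tokens whose first token is not an operation
  keyword define a sequence (``T7_Universal  TAATACGACTCACTATAGGG``); an
  optional leading kind keyword (``oligo``/``dsDNA``/``plasmid``) overrides
  structural inference.  ``#`` and ``//`` open comment lines.
* **JSON** — ``{"steps": [...], "sequences": {...}}`` with full
  Polynucleotide detail per sequence.  The normative dialect is the schema
  document shipped at ``cfsim/data/cf_schema.json``.

The final product of a CF is the product of its last step.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

from .dna import Chem, Polynucleotide, Protrusion, check_iupac
from .errors import ParseError, SchemaError

OPERATIONS = ("PCR", "Digest", "Ligate", "GoldenGate", "Gibson", "Transform")
_OP_BY_KEY = {op.lower(): op for op in OPERATIONS}
_KIND_KEYWORDS = {"oligo": "oligo", "dsdna": "dsDNA", "plasmid": "plasmid"}

#: Below this length a bare sequence is taken to be a single-stranded oligo;
#: at or above it, a blunt double-stranded DNA.
STRANDEDNESS_LENGTH_THRESHOLD = 100


@dataclass
class Step:
    """One cloning operation: keyword, input names, parameters, product name."""

    operation: str
    inputs: list[str]
    product: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.operation not in OPERATIONS:
            raise ParseError(f"Unknown operation {self.operation!r}")
        if not self.product:
            raise ParseError(f"{self.operation} step has an empty product name")
        frag = self.params.get("fragSelect")
        if frag is not None and frag < 0:
            raise ParseError(f"fragSelect must be >= 0, got {frag}")


@dataclass
class ConstructionFile:
    steps: list[Step] = field(default_factory=list)
    sequences: dict[str, Polynucleotide] = field(default_factory=dict)
    name: str = ""

    @property
    def final_product(self) -> str:
        """The singular output of the file: the product of the last step."""
        return self.steps[-1].product if self.steps else ""

    @property
    def step_products(self) -> set[str]:
        return {s.product for s in self.steps}

    def external_inputs(self) -> set[str]:
        """Input names not defined by an earlier step or a local sequence."""
        produced: set[str] = set()
        external: set[str] = set()
        for step in self.steps:
            for name in step.inputs:
                if name not in produced and name not in self.sequences:
                    external.add(name)
            produced.add(step.product)
        return external


def infer_polynucleotide(name: str, raw: str, hint: str | None = None) -> Polynucleotide:
    """Build a full Polynucleotide from a bare name/sequence pair.

    An explicit *hint* (``oligo``/``dsDNA``/``plasmid``) wins; otherwise
    sequences shorter than 100 bases are taken to be single-stranded oligos
    and longer ones blunt double-stranded DNAs — the split that covers
    nearly all real cloning inputs.
    """
    seq = check_iupac(raw, f"sequence {name!r}")
    if hint is not None and hint.lower() not in _KIND_KEYWORDS:
        raise ParseError(f"Unknown sequence kind {hint!r} for {name!r}")
    kind = _KIND_KEYWORDS[hint.lower()] if hint else (
        "oligo" if len(seq) < STRANDEDNESS_LENGTH_THRESHOLD else "dsDNA"
    )
    if kind == "plasmid":
        return Polynucleotide.plasmid(seq, name=name)
    if kind == "oligo":
        return Polynucleotide.oligo(seq, name=name)
    return Polynucleotide.blunt_dsdna(seq, name=name)


# ---------------------------------------------------------------------------
# Shorthand
# ---------------------------------------------------------------------------

_NUMBER_RE = re.compile(r"^\d+(\.\d+)?$")


def _parse_step_tokens(op: str, tokens: list[str], lineno: int) -> Step:
    """Tokens exclude the operation keyword; the last token is the product."""
    def fail(msg):
        raise ParseError(f"Line {lineno}: {msg}")

    if len(tokens) < 2:
        fail(f"{op} step needs at least an input and a product")
    product = tokens[-1]
    body = tokens[:-1]
    params: dict = {}
    if op == "PCR":
        if len(body) == 4:
            if not body[3].isdigit():
                fail(f"PCR size parameter must be an integer, got {body[3]!r}")
            params["product_size"] = int(body[3])
            body = body[:3]
        if len(body) != 3:
            fail("PCR takes forward primer, reverse primer, template, [size]")
        inputs = body
    elif op == "Digest":
        if len(body) < 3:
            fail("Digest takes dna, enzyme[,enzyme...], fragSelect")
        if not body[-1].isdigit():
            fail(f"Digest fragSelect must be an integer, got {body[-1]!r}")
        params["fragSelect"] = int(body[-1])
        enzymes: list[str] = []
        for tok in body[1:-1]:
            enzymes.extend(e for e in tok.split(",") if e)
        if not enzymes:
            fail("Digest needs at least one enzyme")
        params["enzymes"] = enzymes
        inputs = [body[0]]
    elif op == "GoldenGate":
        if len(body) < 2:
            fail("GoldenGate takes dna [dna...] enzyme")
        params["enzyme"] = body[-1]
        inputs = body[:-1]
    elif op in ("Ligate", "Gibson"):
        inputs = body
    elif op == "Transform":
        if len(body) < 2:
            fail("Transform takes dna, host, [antibiotic], [temperature]")
        inputs = [body[0]]
        params["host"] = body[1]
        extras = body[2:]
        if extras and _NUMBER_RE.match(extras[-1]):
            params["temperature"] = float(extras[-1])
            extras = extras[:-1]
        if extras:
            params["antibiotic"] = extras[0]
            extras = extras[1:]
        if extras:
            fail(f"Transform has unexpected tokens {extras}")
    else:  # pragma: no cover - OPERATIONS is closed
        fail(f"Unhandled operation {op}")
    return Step(operation=op, inputs=list(inputs), product=product, params=params)


def parse_shorthand(text: str, name: str = "") -> ConstructionFile:
    """Parse CF shorthand text into a :class:`ConstructionFile`."""
    cf = ConstructionFile(name=name)
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("//"):
            continue
        tokens = line.split()
        first = tokens[0].lower()
        if first in _OP_BY_KEY:
            if len(tokens) < 3:
                raise ParseError(
                    f"Line {lineno}: {tokens[0]} step has too few tokens ({len(tokens)})"
                )
            cf.steps.append(_parse_step_tokens(_OP_BY_KEY[first], tokens[1:], lineno))
        elif first in _KIND_KEYWORDS and len(tokens) == 3:
            cf.sequences[tokens[1]] = infer_polynucleotide(tokens[1], tokens[2], hint=first)
        elif len(tokens) == 2:
            cf.sequences[tokens[0]] = infer_polynucleotide(tokens[0], tokens[1])
        else:
            raise ParseError(
                f"Line {lineno}: unknown operation {tokens[0]!r} "
                f"(not a step keyword and not a 'name sequence' line)"
            )
    return cf


def _step_tokens(step: Step) -> list[str]:
    if step.operation == "PCR":
        toks = list(step.inputs)
        if "product_size" in step.params:
            toks.append(str(step.params["product_size"]))
    elif step.operation == "Digest":
        toks = [step.inputs[0], ",".join(step.params["enzymes"]), str(step.params["fragSelect"])]
    elif step.operation == "GoldenGate":
        toks = list(step.inputs) + [step.params["enzyme"]]
    elif step.operation == "Transform":
        toks = [step.inputs[0], step.params["host"]]
        if "antibiotic" in step.params:
            toks.append(step.params["antibiotic"])
        if "temperature" in step.params:
            temp = step.params["temperature"]
            toks.append(str(int(temp)) if float(temp).is_integer() else str(temp))
    else:
        toks = list(step.inputs)
    return [step.operation] + toks + [step.product]


def _sequence_kind(p: Polynucleotide) -> str:
    if p.is_circular:
        return "plasmid"
    return "dsDNA" if p.is_double_stranded else "oligo"


def write_shorthand(cf: ConstructionFile) -> str:
    """Serialise to shorthand; steps first, then typed sequence lines."""
    lines = ["\t".join(_step_tokens(s)) for s in cf.steps]
    for name, poly in cf.sequences.items():
        lines.append("\t".join([_sequence_kind(poly), name, poly.sequence]))
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# JSON
# ---------------------------------------------------------------------------

def _ext_to_json(ext: str, kind: Protrusion) -> str:
    # 3' protrusions are serialised with a '-' prefix on the extension string.
    return "-" + ext if kind is Protrusion.THREE_PRIME else ext


def _ext_from_json(value: str, name: str) -> tuple[str, Protrusion]:
    if not isinstance(value, str):
        raise SchemaError(f"Sequence {name!r}: extension must be a string")
    if value.startswith("-"):
        ext = value[1:]
        if not ext:
            raise SchemaError(f"Sequence {name!r}: '-' prefix needs an extension sequence")
        return ext, Protrusion.THREE_PRIME
    return value, (Protrusion.FIVE_PRIME if value else Protrusion.BLUNT)


def polynucleotide_to_json(p: Polynucleotide) -> dict:
    return {
        "sequence": p.sequence,
        "ext5": _ext_to_json(p.ext5, p.ext5_kind),
        "ext3": _ext_to_json(p.ext3, p.ext3_kind),
        "mod_ext5": p.mod_ext5.value if p.mod_ext5 else None,
        "mod_ext3": p.mod_ext3.value if p.mod_ext3 else None,
        "isDoubleStranded": p.is_double_stranded,
        "isCircular": p.is_circular,
    }


def polynucleotide_from_json(name: str, obj: dict) -> Polynucleotide:
    if not isinstance(obj, dict) or "sequence" not in obj:
        raise SchemaError(f"Sequence {name!r}: expected an object with a 'sequence' member")
    ext5, ext5_kind = _ext_from_json(obj.get("ext5", ""), name)
    ext3, ext3_kind = _ext_from_json(obj.get("ext3", ""), name)
    def chem(key):
        v = obj.get(key)
        if v is None:
            return None
        try:
            return Chem(v)
        except ValueError:
            raise SchemaError(f"Sequence {name!r}: bad {key} value {v!r}") from None
    try:
        return Polynucleotide(
            sequence=obj["sequence"],
            ext5=ext5,
            ext3=ext3,
            ext5_kind=ext5_kind,
            ext3_kind=ext3_kind,
            mod_ext5=chem("mod_ext5"),
            mod_ext3=chem("mod_ext3"),
            is_double_stranded=bool(obj.get("isDoubleStranded", True)),
            is_circular=bool(obj.get("isCircular", False)),
            name=name,
        )
    except SchemaError as exc:
        raise SchemaError(f"Sequence {name!r}: {exc}") from None


_STEP_PARAM_KEYS = {
    "PCR": {"product_size"},
    "Digest": {"enzymes", "fragSelect"},
    "GoldenGate": {"enzyme"},
    "Ligate": set(),
    "Gibson": set(),
    "Transform": {"host", "antibiotic", "temperature"},
}


def step_to_json(step: Step) -> dict:
    obj = {"operation": step.operation, "inputs": list(step.inputs)}
    for key in sorted(_STEP_PARAM_KEYS[step.operation]):
        if key in step.params:
            obj[key] = step.params[key]
    obj["product"] = step.product
    return obj


def step_from_json(obj: dict, index: int) -> Step:
    if not isinstance(obj, dict):
        raise SchemaError(f"Step {index}: expected an object")
    for member in ("operation", "inputs", "product"):
        if member not in obj:
            raise SchemaError(f"Step {index}: missing member {member!r}")
    op = str(obj["operation"])
    op_canonical = _OP_BY_KEY.get(op.lower())
    if op_canonical is None:
        raise SchemaError(f"Step {index}: unknown operation {op!r}")
    params = {k: obj[k] for k in _STEP_PARAM_KEYS[op_canonical] if k in obj}
    if "fragSelect" in params:
        params["fragSelect"] = int(params["fragSelect"])
    try:
        return Step(
            operation=op_canonical,
            inputs=[str(x) for x in obj["inputs"]],
            product=str(obj["product"]),
            params=params,
        )
    except ParseError as exc:
        raise SchemaError(f"Step {index}: {exc}") from None


def parse_cf_json(doc: "str | dict", name: str = "") -> ConstructionFile:
    """Parse a CF JSON document (text or already-decoded object)."""
    if isinstance(doc, str):
        try:
            doc = json.loads(doc)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"Invalid JSON: {exc}") from None
    if not isinstance(doc, dict):
        raise SchemaError("CF JSON must be an object")
    for member in ("steps", "sequences"):
        if member not in doc:
            raise SchemaError(f"CF JSON is missing the {member!r} member")
    if not isinstance(doc["steps"], list):
        raise SchemaError("'steps' must be an array")
    if not isinstance(doc["sequences"], dict):
        raise SchemaError("'sequences' must be an object")
    cf = ConstructionFile(name=name)
    for i, sobj in enumerate(doc["steps"]):
        cf.steps.append(step_from_json(sobj, i))
    for seq_name, sobj in doc["sequences"].items():
        cf.sequences[seq_name] = polynucleotide_from_json(seq_name, sobj)
    return cf


def write_cf_json(cf: ConstructionFile, indent: int | None = 2) -> str:
    doc = {
        "steps": [step_to_json(s) for s in cf.steps],
        "sequences": {name: polynucleotide_to_json(p) for name, p in cf.sequences.items()},
    }
    return json.dumps(doc, indent=indent)
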