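"""Exception hierarchy for construction-file parsing and simulation.

Every simulation failure derives from :class:`CFError` so that a runner can
terminate a construction file at the failing step and report a single,
actionable message.
"""


class CFError(Exception):
    """Base class for all construction-file errors."""


class AlphabetError(CFError):
    """A sequence contains a character outside the IUPAC DNA alphabet."""


class ParseError(CFError):
    """Shorthand or TSV text could not be parsed."""


class SchemaError(CFError):
    """A CF JSON document violates the schema or a Polynucleotide invariant."""


class UnknownEnzymeError(CFError):
    """An enzyme name is not in the loaded table; carries suggestions."""

    def __init__(self, name: str, suggestions=()):
        self.name = name
        self.suggestions = list(suggestions)
        hint = f" Did you mean: {', '.join(self.suggestions)}?" if self.suggestions else ""
        super().__init__(f"Unknown enzyme {name!r}.{hint}")


class EnzymeFormatError(CFError):
    """A line in an enzyme table could not be parsed."""


class PCRError(CFError):
    """PCR simulation failure (no product, ambiguity, or size mismatch)."""


class NoProductError(PCRError):
    pass


class AmbiguousProductError(PCRError):
    pass


class SizeMismatchError(PCRError):
    pass


class DigestError(CFError):
    """Digestion failure (unsupported substrate, bad fragment index)."""


class LigationError(CFError):
    """Ligation failure (incompatible or unphosphorylated ends, ambiguity)."""


class AssemblyError(CFError):
    """GoldenGate/Gibson failure (re-ligation, site retention, orphan end)."""


class TransformError(CFError):
    """Transformation failure (non-circular DNA)."""


class ExperimentError(CFError):
    """Experiment-level failure (missing sequence, cycle, name collision)."""


class MissingSequenceError(ExperimentError):
    pass


class CycleError(ExperimentError):
    pass


class NameCollisionError(ExperimentError):
    pass


class FixtureError(CFError):
    """A synthetic fixture could not be generated under its constraints."""
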