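"""Exception hierarchy for dcl3dice."""


class DicingCodeError(Exception):
    """Base class for all dcl3dice errors."""


class ComplementarityError(DicingCodeError):
    """Mismatch inside the base-paired region of a duplex."""


class GeometryError(DicingCodeError):
    """Impossible duplex/strand geometry (e.g. paired region < 1 nt)."""


class PreconditionError(DicingCodeError):
    """An operation was called on inputs outside its contract."""


class TemplateError(DicingCodeError):
    """No transcription start site compatible with the requested 5' nucleotide."""


class ProvenanceError(DicingCodeError):
    """A strand lacks the source-coordinate information required."""


class ClassificationError(DicingCodeError):
    """Scenario classification requested for a non Pol IV/RDR2 substrate."""


class ConfigError(DicingCodeError):
    """Malformed or unknown configuration keys."""
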