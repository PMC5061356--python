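"""Exception hierarchy for the pipeline."""


class CbcDelimError(Exception):
    """Base class for all package errors."""


class FormatError(CbcDelimError):
    """A file or string does not conform to its declared format."""


class ValidationError(CbcDelimError):
    """Input violates a domain invariant (duplicate ids, gaps where forbidden, ...)."""


class StructureError(CbcDelimError):
    """A secondary structure is malformed (unbalanced brackets, crossing pairs, short loop)."""


class ProjectionError(CbcDelimError):
    """Template structure cannot be projected onto the alignment."""


class AlphabetError(CbcDelimError):
    """Character outside the {A,C,G,U,N,-} alphabet."""


class ConfigError(CbcDelimError):
    """Simulation or pipeline configuration is infeasible or malformed."""
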