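"""Exception hierarchy.

All package-raised errors derive from :class:`SigstratError` so callers (and
the CLI) can distinguish validation problems (exit code 1) from genuine bugs
(exit code 2).
"""


class SigstratError(Exception):
    """Base class for all errors raised by sigstrat."""


class FormatError(SigstratError):
    """An input file does not have the expected structure (e.g. missing column)."""


class ValidationError(SigstratError):
    """Input data violates a declared invariant (range, duplicate, missingness)."""


class DimensionError(SigstratError):
    """Vectors or matrices with incompatible dimensions."""


class ParameterError(SigstratError):
    """A configuration parameter is out of its admissible range."""


class AlignmentError(SigstratError):
    """Patient sets at the two timepoints cannot be aligned."""


class DegenerateEvidenceError(SigstratError):
    """A Bayes update left zero posterior mass on every class."""
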