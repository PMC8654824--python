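"""Exception hierarchy.

``InputError`` covers malformed user input (bad FASTA, bad headers, bad
configuration) and maps to exit code 1 in the CLI; ``StageError`` covers
failures inside an analysis stage and maps to exit code 2.
"""


class BarcodeEvalError(Exception):
    """Base class for all package errors."""


class InputError(BarcodeEvalError):
    """Malformed or inconsistent user-supplied input."""


class RaggedAlignmentError(InputError):
    """Alignment records do not all share the same column count."""


class DuplicateSampleError(InputError):
    """Two records in one locus share a sample_id."""


class HeaderParseError(InputError):
    """A FASTA header does not follow the configured dialect."""


class StageError(BarcodeEvalError):
    """An analysis stage failed on otherwise well-formed input."""


class UndefinedDistanceError(StageError):
    """An operation that requires fully defined distances met an undefined entry."""
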