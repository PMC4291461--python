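"""Exception hierarchy.

Validation errors (bad inputs, infeasible specs, malformed files) are kept
separate from runtime errors so the command-line layer can map them to
distinct exit codes.
"""


class SnrisoError(Exception):
    """Base class for all package errors."""


class ValidationError(SnrisoError):
    """Invalid configuration, sample sheet, or infeasible synthetic spec."""


class CatalogError(SnrisoError):
    """Problems building the paralog catalog (FASTA content, alignments)."""


class AssignmentError(SnrisoError):
    """Problems during read assignment (malformed FASTQ, bad read length)."""


class EstimationError(SnrisoError):
    """Problems estimating fractions (no informative reads, missing classes)."""
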