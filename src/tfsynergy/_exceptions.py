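"""Package-wide exception types."""


class TFSynergyError(Exception):
    """Base class for all package errors."""


class DataValidationError(TFSynergyError):
    """Raised when an input matrix, label file, or config violates an invariant."""


class InsufficientTFsError(TFSynergyError):
    """Raised when a subpopulation retains fewer than three candidate TFs.

    Subpopulations without enough expressed TFs cannot seed a 3-TF search and
    are skipped (reported, not fatal) by the pipeline drivers.
    """
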