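"""Exception hierarchy for the screen-analysis pipeline.

Every stage raises a subclass of :class:`FflScreenError` so the pipeline
driver can map failures to a stage name and a clean exit code.
"""


class FflScreenError(Exception):
    """Base class for all package errors."""


class SchemaError(FflScreenError):
    """A mandatory column or metadata field is missing from an input table."""


class DuplicateRecordError(FflScreenError):
    """The same (gene, sample) cell appears more than once in an input table."""


class RangeError(FflScreenError):
    """A CT value lies outside the allowed [0, ct_max] range."""


class NormalizationError(FflScreenError):
    """The reference gene is missing in a sample that carries other data."""


class PairingError(FflScreenError):
    """No matched control sample exists for a perturbed stratum."""


class InsufficientDataError(FflScreenError):
    """Too few observations to compute the requested statistic."""


class InsufficientReplicationError(InsufficientDataError):
    """No cell has the K >= 2 replicates needed for a sample variance."""


class BinningError(FflScreenError):
    """Too few records to form the requested number of variance bins."""


class FitError(FflScreenError):
    """Nonlinear fit failed to converge; carries the best iterate."""

    def __init__(self, message, model=None):
        super().__init__(message)
        self.model = model


class ModelError(FflScreenError):
    """The fitted variance model cannot be used (e.g. non-positive variance)."""


class InconsistentCallError(FflScreenError):
    """A feed-forward loop was requested for regulations that are not significant."""


class ConfigError(FflScreenError):
    """Invalid pipeline or simulation configuration."""


class StageError(FflScreenError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, cause):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
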