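"""Exception types shared across the pipeline."""


class MthetError(Exception):
    """Base class for all package errors."""


class CoordinateError(MthetError):
    """A 1-based genomic coordinate falls outside the genome."""


class AlphabetError(MthetError):
    """A sequence contains characters outside the expected alphabet."""


class InsufficientDataError(MthetError):
    """Too few observations for the requested statistic."""


class IncompatibleGenomesError(MthetError):
    """Two containers do not refer to the same genome."""


class ZeroDepthError(MthetError):
    """No quality-passing reads at a position; VAF is undefined there."""


class MissingDataError(MthetError):
    """A required measurement (e.g. a Ct value) is absent."""


class ParameterError(MthetError):
    """A model parameter is outside its valid domain."""


class AnnotationError(MthetError):
    """A variant cannot be classified (e.g. CDS region without frame)."""


class StageError(MthetError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
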