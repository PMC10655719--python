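"""Exception hierarchy shared across the pipeline stages."""


class TmtDiffError(Exception):
    """Base class for all errors raised by this package."""


class DesignError(TmtDiffError):
    """The sample-design table is inconsistent (duplicates, bad reference)."""


class FormatError(TmtDiffError):
    """An input file does not have the documented layout."""


class ValidationError(TmtDiffError):
    """A value violates its documented domain (negative intensity, p > 1, ...)."""


class AmbiguousPeptideError(TmtDiffError):
    """A peptide ion maps to more than one protein accession."""


class NormalizationError(TmtDiffError):
    """Median normalization cannot be performed (e.g. an empty sample)."""


class ContrastError(TmtDiffError):
    """A requested contrast is not available in the fitted records."""


class PipelineError(TmtDiffError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
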