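"""Exception hierarchy shared across the pipeline."""


class TDSError(Exception):
    """Base class for all tdscreen errors."""


class FormatError(TDSError):
    """A file does not conform to the expected dialect (missing columns/sections)."""


class IntegrityError(TDSError):
    """Data violates an invariant: duplicates, negative counts, bad enum values."""


class CrossReferenceError(TDSError):
    """Two artifacts disagree, e.g. a panel gene absent from the probe annotation."""


class NormalizationError(TDSError):
    """A normalization factor cannot be computed (e.g. all-zero controls)."""
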