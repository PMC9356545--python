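"""Exception hierarchy for the pipeline."""


class RhdocallError(Exception):
    """Base class for all package errors."""


class ValidationError(RhdocallError):
    """Malformed or out-of-contract input (bad counts, bad config, bad VCF)."""


class QCError(RhdocallError):
    """A quality-control stage could not be evaluated (e.g. no complete-trio sites)."""


class EstimationError(RhdocallError):
    """Fetal-fraction estimation had no usable sites."""


class PhasingError(RhdocallError):
    """Parental phasing could not be performed (missing proband, no resolvable sites)."""
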