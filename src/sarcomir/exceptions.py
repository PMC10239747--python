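"""Exception hierarchy for sarcomir.

Every error raised by the package derives from :class:`SarcomirError`, so
callers can catch the package's failures with a single ``except`` clause
while still discriminating the specific failure mode.
"""


class SarcomirError(Exception):
    """Base class for all sarcomir errors."""


class ConfigurationError(SarcomirError):
    """A configuration value is invalid; the message names the field."""


class ConsistencyError(SarcomirError):
    """Two artifacts that must come from the same configuration do not."""


class InsufficientReplicationError(SarcomirError):
    """A differential-expression group has fewer than two samples."""


class EmptySignatureError(SarcomirError):
    """None of the requested signature features are present in the matrix."""


class DegenerateSplitError(SarcomirError):
    """A median split placed every sample in a single group."""


class InsufficientOverlapError(SarcomirError):
    """Fewer than three shared samples are available for correlation."""


class MembershipError(SarcomirError):
    """A query gene set is not contained in the declared universe."""


class DependencyError(SarcomirError):
    """A pipeline stage's input artifact is missing; the message names it."""


class ParseError(SarcomirError):
    """A tabular input file is malformed; the message carries the line."""
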