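"""Exception hierarchy for rest-activity rhythm analysis.

Every failure mode has its own class so callers (and the CLI) can
distinguish malformed files from scientifically degenerate inputs.
"""


class RarlabError(Exception):
    """Base class for all package errors."""


class StructuralError(RarlabError):
    """The input file or record violates the format contract
    (non-monotone timestamps, gaps, missing header)."""


class ValidationError(RarlabError):
    """A value violates a domain invariant (e.g. negative activity count)."""


class ParameterError(RarlabError):
    """A configuration or function parameter is out of its legal range."""


class InsufficientDataError(RarlabError):
    """Too little valid data to compute the requested quantity."""


class DegenerateInputError(RarlabError):
    """Input is formally valid but the statistic is undefined on it
    (constant series, zero denominator)."""


class TransformError(RarlabError):
    """A variable transform cannot be applied (e.g. ln of a non-positive
    outcome value)."""


class AccountingError(RarlabError):
    """Participant-flow arithmetic went negative."""


class FitFailureError(RarlabError):
    """Model estimation failed from every starting point."""
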