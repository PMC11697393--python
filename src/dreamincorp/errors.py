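"""Exception hierarchy.

Every malformed input raises a named error; no operation returns a
partially constructed object.
"""


class DreamIncorpError(Exception):
    """Base class for all package errors."""


class ValidationError(DreamIncorpError):
    """A domain object or input file violates an invariant."""


class AssignmentError(ValidationError):
    """A participant's plan->status mapping is not a bijection."""


class EmptyTextError(ValidationError):
    """An operation requiring non-empty text received empty input."""


class BackendError(DreamIncorpError):
    """An external model backend is unavailable or misconfigured."""


class UndefinedSimilarityError(DreamIncorpError):
    """Cosine similarity requested for a zero vector or mismatched dims."""


class DegenerateInputError(DreamIncorpError):
    """A statistical routine received input it cannot test (e.g. empty)."""
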