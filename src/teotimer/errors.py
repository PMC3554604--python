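"""Exception hierarchy shared by all teotimer modules."""


class TeoTimerError(Exception):
    """Base class for all package errors."""


class InvalidInputError(TeoTimerError, ValueError):
    """A precondition on user-supplied input was violated."""


class NotFoundError(TeoTimerError, KeyError):
    """A referenced entity (event id, report field) does not exist."""


class ConflictError(TeoTimerError):
    """An operation would overwrite or contradict recorded information."""

    def __init__(self, message, derivations=None):
        super().__init__(message)
        self.derivations = list(derivations or [])


class ParseError(TeoTimerError, ValueError):
    """A time/duration/periodic expression or document could not be parsed.

    ``token`` names the offending fragment when known.
    """

    def __init__(self, message, token=None):
        super().__init__(message)
        self.token = token


class AmbiguityError(ParseError):
    """An expression admits more than one reading and no context resolves it."""


class NotPeriodicError(ParseError):
    """The expression carries no frequency pattern; caller may fall back."""


class AnchorSelectionError(TeoTimerError):
    """No vaccination anchor event could be identified in a timeline."""


class StructuralError(TeoTimerError):
    """A document or graph violates structural requirements (dangling ids,
    missing mandatory fields)."""

    def __init__(self, message, missing=None):
        super().__init__(message)
        self.missing = list(missing or [])


class InconsistencyError(TeoTimerError):
    """The temporal constraints admit no scenario.

    ``culprits`` carries the offending assertion pair(s) or triangle.
    """

    def __init__(self, message, culprits=None):
        super().__init__(message)
        self.culprits = list(culprits or [])
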