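"""Exception types shared across the package."""


class StreamSpomError(ValueError):
    """Base class for all streamspom errors."""


class ParameterError(StreamSpomError):
    """An argument is outside its admissible range."""


class NetworkStructureError(StreamSpomError):
    """The drainage graph is not a rooted tree (cycle, multiple outlets, ...)."""


class DataError(StreamSpomError):
    """An input series contains invalid values (e.g. negative rainfall)."""


class ContractViolationError(StreamSpomError):
    """A caller-side contract was violated (e.g. a source node is not active)."""


class SizeError(StreamSpomError):
    """A problem size exceeds what an exact method can handle."""
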