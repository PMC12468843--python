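"""Exception hierarchy."""


class DivlocError(Exception):
    """Base class for all package errors."""


class ValidationError(DivlocError, ValueError):
    """Invalid construction input (bad probabilities, malformed tables...)."""


class DomainError(DivlocError, ValueError):
    """Operation called outside its mathematical domain (empty part, zero mass...)."""


class InfeasibleDesignError(DivlocError, ValueError):
    """A null-set design admits no discrete realization with integer atom counts."""


class NumericalError(DivlocError, RuntimeError):
    """Root finding or integration failed; carries diagnostics in the message."""
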