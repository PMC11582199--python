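"""Exception hierarchy.

All user-facing validation failures derive from :class:`InputError` so
callers can distinguish bad inputs from genuine numerical failures.
"""


class HybridFlairError(Exception):
    """Base class for all package errors."""


class InputError(HybridFlairError, ValueError):
    """Invalid or inconsistent user input (shape mismatch, bad labels, ...)."""


class DegenerateInputError(InputError):
    """Structurally valid input on which the operation is undefined
    (empty mask, zero windowed energy, constant reference image, ...)."""


class NumericalError(HybridFlairError, RuntimeError):
    """A numerical routine failed to converge or bracket a root."""
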