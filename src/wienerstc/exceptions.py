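"""Exception hierarchy.

``ValidationError`` (and subclasses) maps to CLI exit code 2;
``DegenerateInputError`` maps to exit code 3.
"""


class WienerSTCError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(WienerSTCError):
    """An input violates a documented precondition (bad shape, value, flag)."""


class DimensionError(ValidationError):
    """Paired arrays disagree in length or width."""


class LagError(ValidationError):
    """The requested lag window does not fit in the recording."""


class ContractError(ValidationError):
    """An object is used outside the contract it was built under.

    Raised e.g. when a covariance computed without response demeaning is
    passed to the Wiener rescaling, which is only valid for a zero-mean
    response.
    """


class DegenerateInputError(WienerSTCError):
    """Structurally valid input on which the quantity is undefined.

    Typical case: a spike train with no spikes, which leaves the
    spike-triggered average and every STC variant undefined.
    """
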