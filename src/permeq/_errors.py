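"""Exception hierarchy.

All errors raised by the package derive from :class:`PermeqError` so callers
can catch the package's failures without masking programming errors.
"""


class PermeqError(Exception):
    """Base class for all permeq errors."""


class RateValidationError(PermeqError):
    """A transition rate evaluated to a negative value."""

    def __init__(self, i: int, j: int, t: float, value: float):
        self.i, self.j, self.t, self.value = i, j, t, value
        super().__init__(
            f"rate p_{i + 1},{j + 1} evaluated to {value!r} < 0 at t={t!r}"
        )


class ConfigurationError(PermeqError):
    """A model or run configuration is inconsistent or incomplete."""


class CapacityError(PermeqError):
    """The requested model exceeds the configured size budget."""


class NumericalError(PermeqError):
    """An integrator or quadrature failed to converge."""


class DegenerateSystemError(PermeqError):
    """Every point is periodic; the requested unique object does not exist."""
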