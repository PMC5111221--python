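"""Exception hierarchy for shallowcn.

All package errors derive from :class:`ShallowCNError` so callers can catch
one base class; each subclass also derives from the closest builtin so that
generic ``except ValueError`` style handling keeps working.
"""


class ShallowCNError(Exception):
    """Base class for all shallowcn errors."""


class DegenerateInputError(ShallowCNError, ValueError):
    """Input is structurally valid but too sparse/empty for the operation."""


class FitError(ShallowCNError, RuntimeError):
    """A model fit produced non-finite or unusable results."""


class PlacementError(ShallowCNError, RuntimeError):
    """Random event placement failed after bounded retries."""


class ConfigurationError(ShallowCNError, ValueError):
    """Inputs are mutually inconsistent (e.g. grid mismatch between tracks)."""


class FormatError(ShallowCNError, ValueError):
    """A file or stream violates its declared format (e.g. unsorted reads)."""


class AccountingError(ShallowCNError, ValueError):
    """Base-pair bookkeeping produced an impossible (negative) quantity."""
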