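"""Exception hierarchy.

All package errors derive from :class:`GrowthPeaksError` so callers can catch
one base class; the CLI maps each category to a distinct exit message.
"""


class GrowthPeaksError(Exception):
    """Base class for all growthpeaks errors."""


class InvalidInputError(GrowthPeaksError, ValueError):
    """A parameter or data structure violates a precondition."""


class FormatError(GrowthPeaksError, ValueError):
    """A file could not be parsed in the declared dialect."""


class NumericalError(GrowthPeaksError, RuntimeError):
    """An integrator or optimizer failed to meet its tolerances."""


class DegeneratePeakError(GrowthPeaksError, ValueError):
    """A curve has no well-defined peak (e.g. all values equal)."""
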