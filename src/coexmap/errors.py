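"""Exception hierarchy for coexmap.

All package errors derive from :class:`CoexmapError` so callers can catch
one base class; the subclasses distinguish malformed files, missing
features, degenerate numeric input, and invalid configuration.
"""


class CoexmapError(Exception):
    """Base class for all coexmap errors."""


class FormatError(CoexmapError, ValueError):
    """A file or string does not conform to its expected format."""


class MissingFeatureError(CoexmapError, KeyError):
    """A requested gene/feature or sample is absent from a container."""


class DegenerateInputError(CoexmapError, ValueError):
    """Numeric input on which the requested statistic is undefined
    (constant vector, empty gene set, zero-variance null, ...)."""


class SizeError(CoexmapError, ValueError):
    """Input too small (or a requested k too large) for the operation."""


class ConfigurationError(CoexmapError, ValueError):
    """A simulation spec or option set violates its invariants."""


class EmptySelectionError(CoexmapError, ValueError):
    """A sample/feature predicate matched nothing."""


class DegenerateWindowError(CoexmapError, ValueError):
    """A cis window around a target contains no other usable gene."""


class InsufficientNullPoolError(CoexmapError, ValueError):
    """The same-chromosome null pool is smaller than the hit pool."""
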