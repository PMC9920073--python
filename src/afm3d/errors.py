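"""Exception hierarchy for afm3d.

All package-specific errors derive from :class:`AFM3DError` so callers can
catch everything with one clause; subclasses discriminate between user input
problems, file-format problems and numerical failures.
"""


class AFM3DError(Exception):
    """Base class for all afm3d errors."""


class GeometryMismatchError(AFM3DError, ValueError):
    """An operation received an indenter geometry of the wrong kind."""


class DomainError(AFM3DError, ValueError):
    """A physical argument (depth, force, modulus...) is out of its valid range."""


class ParameterError(AFM3DError, ValueError):
    """An invalid scalar parameter (spring constant, Poisson ratio...)."""


class ConfigurationError(AFM3DError, ValueError):
    """A run configuration is inconsistent or incomplete."""


class FormatError(AFM3DError, ValueError):
    """A file could not be parsed in the documented dialect."""


class DataError(AFM3DError, ValueError):
    """Data content violates an invariant (too few samples, non-finite...)."""


class ConsistencyError(AFM3DError, ValueError):
    """Cross-file or cross-field inconsistency (e.g. manifest vs data shape)."""


class WindowError(DataError):
    """Too few samples fall inside the requested fitting window."""


class NumericalError(AFM3DError, RuntimeError):
    """A numerical routine failed to converge; carries diagnostics in args."""


class DegenerateDistributionError(AFM3DError, ValueError):
    """A density was requested for a zero-width (sigma = 0) distribution."""
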