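"""Exception hierarchy.

User-facing errors derive from :class:`PolarsigError`; the CLI maps them to
exit code 1, anything else to exit code 2.
"""


class PolarsigError(Exception):
    """Base class for expected, user-actionable errors."""


class MeshValidationError(PolarsigError):
    """A cell mesh violates its invariants (empty/overlapping segments...)."""


class DegenerateGeometryError(PolarsigError):
    """Requested cell geometry cannot form a rod (length < 3x width)."""


class PlacementError(PolarsigError):
    """The simulated field is too small to place all requested cells."""


class ZeroSignalError(PolarsigError):
    """A cell has no fluorescent signal; normalization is undefined."""


class NoBackgroundError(PolarsigError):
    """Image fully covered by cells; no background estimate possible."""


class NoDivisionError(PolarsigError):
    """The track contains no division event ('no event')."""


class ConfigError(PolarsigError):
    """Invalid or incomplete pipeline configuration."""
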