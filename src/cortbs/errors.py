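"""Exception hierarchy for the CortBS pipeline.

Exit-code mapping used by the CLI: :class:`InputError` -> 1,
:class:`QualityError` -> 2.
"""


class CortBSError(Exception):
    """Base class for all package errors."""


class InputError(CortBSError, ValueError):
    """Invalid or rejected input (bad values, schema violations, band mismatch)."""


class ConfigurationError(InputError):
    """Invalid acquisition / pipeline configuration."""


class SchemaError(InputError):
    """A file does not conform to the expected dialect or column schema."""


class QualityError(CortBSError):
    """A quality gate failed (e.g. no valid periosteal surface)."""


class NoValidSurfaceError(QualityError):
    """No beam passed the surface-detection quality criteria."""


class EstimationError(CortBSError):
    """A spectral estimate could not be formed (e.g. too few depth bins)."""


class InversionError(CortBSError):
    """The pore-diameter inversion received degenerate input."""
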