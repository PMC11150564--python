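"""Exception hierarchy for the dtialps pipeline.

Every error raised by the package derives from :class:`DtialpsError`, so
callers can catch pipeline failures without catching programming errors.
"""


class DtialpsError(Exception):
    """Base class for all dtialps errors."""


class FormatError(DtialpsError, ValueError):
    """Malformed input text or file (wrong shape, non-numeric, bad header)."""


class ValidationError(DtialpsError, ValueError):
    """Input parses but violates a domain invariant."""


class SchemaError(DtialpsError, ValueError):
    """A required column or field is missing from a table."""


class MaskingError(DtialpsError, RuntimeError):
    """Brain/object masking produced an empty or degenerate foreground."""


class EstimationError(DtialpsError, RuntimeError):
    """Tensor estimation cannot proceed (rank-deficient design, etc.)."""


class PlacementError(DtialpsError, ValueError):
    """An ROI falls outside the usable image support."""


class ConfigError(DtialpsError, ValueError):
    """An analysis configuration is incomplete or inconsistent."""


class SelectionError(DtialpsError, RuntimeError):
    """No voxel in an ROI satisfies the selection rule."""


class DataQualityError(DtialpsError, RuntimeError):
    """Extracted quantities are outside their physically admissible range."""


class InferenceError(DtialpsError, RuntimeError):
    """Voxelwise inference cannot run (empty skeleton, too few permutations)."""


class SpecError(DtialpsError, ValueError):
    """A synthetic-data specification is internally inconsistent."""
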