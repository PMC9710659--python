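"""Exception hierarchy.

Degenerate geometry inside featurization is normally *masked* rather than
raised (partial structures must survive the pipeline); the exceptions here
are for contract violations at API boundaries.
"""


class GeosecError(Exception):
    """Base class for all package errors."""


class FormatError(GeosecError):
    """A file could not be interpreted in the expected format."""


class ValidationError(GeosecError):
    """An argument violates an operation's contract."""


class ConfigError(GeosecError):
    """Inconsistent run configuration (e.g. feature-mode mismatch)."""


class DegenerateGeometryError(GeosecError):
    """Collinear or coincident points make an angle undefined."""


class GeometryInconsistencyError(GeosecError):
    """Distances are not realizable in Euclidean space (|cos| > 1)."""


class InsufficientStructureError(GeosecError):
    """Too few residues/atoms for the requested construction."""
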