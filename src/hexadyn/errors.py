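"""Exception hierarchy shared by all analysis modules."""


class HexadynError(Exception):
    """Base class for all package errors."""


class FormatError(HexadynError):
    """A file could not be parsed under the named standard."""


class StructureError(HexadynError):
    """Inconsistent structure, e.g. atom-count mismatch across models."""


class SelectionError(HexadynError):
    """A frame/atom selection resolved to an empty or invalid subset."""


class ParameterError(HexadynError):
    """A parameter outside its physically meaningful range."""


class GeometryError(HexadynError):
    """Degenerate geometry (too few atoms, collinear points, empty grid)."""
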