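"""Exception hierarchy shared across the package."""


class TactileMeshError(Exception):
    """Base class for all errors raised by tactilemesh."""


class ParameterError(TactileMeshError, ValueError):
    """A parameter violates a documented invariant."""


class UnsupportedImageError(TactileMeshError):
    """Input file could not be decoded as a supported raster image."""


class DegenerateImageError(TactileMeshError):
    """Image is too small to build a surface from (needs >= 2x2 pixels)."""


class MaskError(TactileMeshError):
    """A mask operation removed all printable content."""


class MeshValidationError(TactileMeshError):
    """A mesh failed the watertight / orientation validation."""


class StlFormatError(TactileMeshError):
    """An STL file is corrupt or does not follow the binary/ASCII layout."""


class PlacementError(TactileMeshError):
    """Braille dots fall outside the included, flat margin region."""


class PackingError(TactileMeshError):
    """Synthetic object placement could not satisfy the separation constraint."""


class PipelineError(TactileMeshError):
    """A generation pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
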