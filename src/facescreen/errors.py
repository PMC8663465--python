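"""Exception hierarchy shared across the pipeline stages."""


class FaceScreenError(Exception):
    """Base class for all package-specific errors."""


class NoFaceError(FaceScreenError):
    """Raised when face detection finds no face in an image.

    Deliberately distinct from I/O errors so callers can tell an unreadable
    file from a readable frame that simply contains no face.
    """


class DegenerateGeometryError(FaceScreenError):
    """Raised when a geometric quantity is undefined for the input
    (coincident points, zero-length baseline, zero inter-ocular distance)."""


class SchemaError(FaceScreenError):
    """Raised when a landmark file does not conform to the ibug68-v1 schema."""


class ConfigurationError(FaceScreenError):
    """Raised when a required backend or setting is missing or invalid."""


class LayoutMismatchError(FaceScreenError):
    """Raised when a feature vector does not match a trained model's layout."""


class UndefinedCorrelationError(FaceScreenError):
    """Raised when a correlation is requested for a zero-variance input."""
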