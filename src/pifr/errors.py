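"""Exception hierarchy shared across the package."""


class PifrError(Exception):
    """Base class for all package-specific errors."""


class StreamParseError(PifrError):
    """A keypoint stream record could not be parsed; names the offending line/record."""


class SchemaError(PifrError):
    """A record violates the skeleton schema (e.g. keypoint count != 17)."""


class StreamIntegrityError(PifrError):
    """Duplicate (track_id, frame_index) or other stream-level inconsistency."""


class MissingKeypointError(PifrError):
    """A required keypoint is below the visibility threshold."""


class DegenerateGeometryError(PifrError):
    """A required vector has zero length, so the angle is undefined."""


class ConfigError(PifrError):
    """Invalid or unknown configuration value."""


class SequencingError(PifrError):
    """Frame indices fed to the temporal engine are not strictly increasing."""


class ModelIOError(PifrError):
    """A model artifact could not be saved or loaded."""
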