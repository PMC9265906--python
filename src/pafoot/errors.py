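"""Exception hierarchy shared across the package."""


class PafootError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PafootError):
    """A file does not conform to the expected dialect."""


class MissingMarkerError(PafootError):
    """One or more required landmarks are absent from a trial.

    ``missing`` lists the absent label names.
    """

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"missing required marker(s): {', '.join(self.missing)}")


class DegenerateGeometryError(PafootError):
    """Marker geometry does not define the requested construction
    (collinear plane points, coincident attachment points, ...)."""


class ConfigError(PafootError):
    """Invalid subject/analysis configuration."""
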