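"""Exception hierarchy."""


class BoutonsortError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BoutonsortError):
    """Invalid specification, configuration, or parameter value."""


class GeometryError(BoutonsortError):
    """Sampling geometry does not fit the image stack."""


class DataIntegrityError(BoutonsortError):
    """Inconsistent or incomplete input records."""


class ModelingError(BoutonsortError):
    """Mixture fitting failed or was requested on unsuitable data."""


class InsufficientDataError(ModelingError):
    """Too few observations for the requested model."""


class NoCrossingError(BoutonsortError):
    """Weighted component densities do not cross between the two means."""

    def __init__(self, message, roots=()):
        super().__init__(message)
        self.roots = tuple(roots)
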