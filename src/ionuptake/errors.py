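"""Exception hierarchy shared across the pipeline."""


class IonUptakeError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(IonUptakeError, ValueError):
    """Invalid domain object (negative concentration, bad lengths, ...)."""


class FormatError(IonUptakeError, ValueError):
    """A file does not match its declared tabular layout."""


class ConfigurationError(IonUptakeError, ValueError):
    """A rule or config refers to something that does not exist."""


class FitError(IonUptakeError, ValueError):
    """A model fit cannot be attempted on the given data."""
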