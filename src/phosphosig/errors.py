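"""Exception hierarchy shared across the package."""


class PhosphosigError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PhosphosigError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(PhosphosigError):
    """A record violates a domain invariant (alphabet, central residue, ...)."""


class CoordinateError(PhosphosigError):
    """A site position falls outside its protein."""


class UsageError(PhosphosigError):
    """An operation was called with inconsistent or unsupported arguments."""


class ConfigError(PhosphosigError):
    """A study design or simulation configuration is internally inconsistent."""
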