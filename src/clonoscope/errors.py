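"""Exception types shared across the package."""


class ClonoscopeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ClonoscopeError):
    """A cohort or analysis configuration field is invalid.

    The message always names the offending field.
    """


class GermlineError(ClonoscopeError):
    """A V gene could not be resolved to germline CDR loop sequences."""


class SequenceError(ClonoscopeError):
    """A CDR3 sequence contains a character outside the 20-letter amino-acid alphabet."""
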