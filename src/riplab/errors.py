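"""Exception hierarchy shared by all pipeline stages."""


class RiplabError(Exception):
    """Base class for all riplab errors."""


class ConfigurationError(RiplabError):
    """A simulator or stage configuration is invalid; the message names the field."""


class InputError(RiplabError):
    """Input data violate a schema or invariant."""


class CalibrationError(RiplabError):
    """A calibrating control gene is missing or undetected; the message names it."""


class GenerationError(RiplabError):
    """A synthetic-data generator could not satisfy its constraints."""


class UndefinedIndexError(RiplabError):
    """A behavioral index is undefined for the given inputs (e.g. CIn = 0)."""
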