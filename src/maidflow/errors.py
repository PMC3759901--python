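"""Exception hierarchy for maidflow."""


class MaidflowError(Exception):
    """Base class for all maidflow errors."""


class DesignError(MaidflowError):
    """Study design is inconsistent with the data (missing samples, bad labels)."""


class ParseError(MaidflowError):
    """A file could not be parsed; carries row/column coordinates where known."""


class ValidationError(MaidflowError):
    """A value violates a domain invariant (e.g. negative Ct, n_algorithms > 10)."""


class ConfigurationError(MaidflowError):
    """Parameters are inconsistent with the requested operation."""
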