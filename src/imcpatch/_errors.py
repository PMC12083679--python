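"""Exception types shared across the pipeline."""


class FormatError(ValueError):
    """An input file does not have the structure it claims (page counts, columns...)."""


class ConfigurationError(ValueError):
    """A parameter is missing or outside its valid range."""


class StateError(RuntimeError):
    """An operation was called out of order (e.g. QC flagging before scaling)."""


class InsufficientDataError(ValueError):
    """Too few observations to run an estimator."""


class NotExpressed(ValueError):
    """A qPCR quantity involves a Ct flagged negative for expression."""
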