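"""Exception hierarchy shared across the pipeline."""


class CrosscleanError(Exception):
    """Base class for all crossclean errors."""


class ParseError(CrosscleanError):
    """A sequence file could not be parsed."""


class DuplicateIdError(CrosscleanError):
    """A transcript or sample identifier was registered twice."""


class ConfigurationError(CrosscleanError):
    """Invalid parameters or an unusable sample manifest."""


class ConsistencyError(CrosscleanError):
    """Internal data structures disagree (missing calls, id mismatches...)."""
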