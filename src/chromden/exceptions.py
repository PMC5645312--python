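"""Exception hierarchy for chromden."""


class ChromdenError(Exception):
    """Base class for all chromden errors."""


class InvalidSpecError(ChromdenError, ValueError):
    """A generator or parameter specification violates its invariants."""


class FormatError(ChromdenError, ValueError):
    """A file could not be parsed in the declared dialect."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class OutOfRangeError(ChromdenError, ValueError):
    """A coordinate or index falls outside the covered genomic range."""


class InsufficientDataError(ChromdenError, ValueError):
    """Too few observations for the requested statistic."""


class ConfigurationError(ChromdenError, ValueError):
    """Pipeline configuration is inconsistent or incomplete."""
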