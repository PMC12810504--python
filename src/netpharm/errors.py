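"""Exception hierarchy shared across the pipeline stages."""


class NetpharmError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(NetpharmError):
    """Raised when an input violates a documented precondition."""


class ParseError(NetpharmError):
    """Raised on malformed input files; carries the offending line number."""

    def __init__(self, message: str, path: str | None = None,
                 line_number: int | None = None):
        self.path = path
        self.line_number = line_number
        loc = ""
        if path is not None:
            loc += f" [{path}"
            if line_number is not None:
                loc += f":{line_number}"
            loc += "]"
        super().__init__(message + loc)
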