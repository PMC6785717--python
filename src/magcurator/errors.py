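"""Exception hierarchy shared across the toolkit."""


class MagcuratorError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(MagcuratorError, ValueError):
    """A value violates a documented invariant (range, emptiness, duplication)."""


class ParseError(MagcuratorError, ValueError):
    """An on-disk artifact could not be parsed; carries file/line context."""

    def __init__(self, message: str, path=None, line: int | None = None):
        ctx = ""
        if path is not None:
            ctx += f"{path}"
        if line is not None:
            ctx += f":{line}"
        super().__init__(f"{ctx}: {message}" if ctx else message)
        self.path = path
        self.line = line


class IncompatibleSketchError(MagcuratorError, ValueError):
    """Two sketches differ in k, sketch size or hash seed and cannot be compared."""
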