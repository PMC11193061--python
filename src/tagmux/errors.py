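"""Exception hierarchy.

Every user-facing error derives from :class:`TagmuxError` so the CLI can map
any failure to a nonzero exit status with a module-tagged message.
"""


class TagmuxError(Exception):
    """Base class for all tagmux errors."""


class ConfigError(TagmuxError):
    """Invalid or malformed configuration file."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class TagIndexError(TagmuxError):
    """Tag index construction failed (e.g. variant enumeration blow-up)."""


class CapacityError(TagmuxError):
    """The 32-bit combination ID space is exhausted."""


class BarcodeFormatError(TagmuxError):
    """A final-barcode string is not 16 ACGT characters."""


class StreamError(TagmuxError):
    """Malformed or desynchronized FASTQ input."""


class ExtractionFailed(TagmuxError):
    """A configured extraction window falls outside the read or its anchor
    tag was never identified; the read is routed to the unassigned stream."""

    def __init__(self, name: str, reason: str):
        self.name = name
        super().__init__(f"extraction '{name}' failed: {reason}")


class GeneratorError(TagmuxError):
    """The synthetic-read generator cannot realize the requested structure."""
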