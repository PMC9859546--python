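"""Exception hierarchy shared by all assessment stages.

Every error raised on purpose by this package derives from :class:`MateError`
so callers (and the CLI) can distinguish bad inputs from genuine bugs.
"""


class MateError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(MateError, ValueError):
    """An input value violates a documented invariant or range."""


class FormatError(MateError):
    """A file could not be parsed; the message names the offending line."""


class ChannelLookupError(MateError, KeyError):
    """A requested channel is absent from a trace.

    ``str(err)`` lists every missing channel so a wrong channel map is
    diagnosed in one pass.
    """

    def __init__(self, missing, available=None):
        self.missing = list(missing)
        self.available = sorted(available) if available is not None else None
        msg = "missing channel(s): " + ", ".join(self.missing)
        if self.available is not None:
            msg += f" (available: {', '.join(self.available)})"
        super().__init__(msg)

    def __str__(self):  # KeyError quotes its arg; keep the readable message
        return self.args[0]


class ConfigurationError(MateError):
    """A threshold table or coefficient file is unusable (e.g. empty)."""
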