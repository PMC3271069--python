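"""Exception hierarchy shared by all ecomics tools.

The CLI maps these onto process exit codes: usage errors exit 2 (click),
:class:`FormatError` exits 3, and I/O failures exit 4.
"""


class EcomicsError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(EcomicsError):
    """An input file violates its documented dialect."""
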