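"""Exception hierarchy shared across the package."""


class SxmergeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SxmergeError):
    """A reflection or manifest file violates the expected text dialect."""


class MissingHeaderError(FormatError):
    """A mandatory header keyword is absent from a reflection file."""


class UnsupportedSpaceGroupError(SxmergeError):
    """The requested space group is not in the bundled operator table."""


class UndefinedModelError(SxmergeError):
    """A fit (Wilson B, error model) cannot be defined on the given data."""
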