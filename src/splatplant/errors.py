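"""Exception hierarchy shared across the package.

CLI exit-code mapping: FormatError -> 2, EmptyResultError -> 3, anything
else -> 1.
"""


class SplatplantError(Exception):
    """Base class for all package errors."""


class FormatError(SplatplantError):
    """A file does not conform to the expected on-disk layout."""


class EmptyResultError(SplatplantError):
    """An operation removed every element (e.g. prefilter emptied a scene)."""
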