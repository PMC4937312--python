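"""Exception hierarchy.

``ValidationError`` covers malformed inputs/configs (CLI exit code 1),
everything else raised at run time maps to exit code 2.
"""


class SirnascopeError(Exception):
    """Base class for package errors."""


class ValidationError(SirnascopeError, ValueError):
    """Invalid input, configuration or coordinate arithmetic."""


class DegenerateLibraryError(SirnascopeError):
    """A sample library whose effective size T - K is not positive."""
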