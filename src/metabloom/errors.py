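"""Exception hierarchy shared across the package."""


class MetabloomError(Exception):
    """Base class for all package-specific errors."""


class TaxonomyError(MetabloomError):
    """Structural problem in a taxonomy (cycle, dangling parent, unknown taxid)."""


class ParameterError(MetabloomError):
    """Invalid parameter value."""


class IndexFormatError(MetabloomError):
    """Corrupt, truncated, or incompatible index file."""


class InputError(MetabloomError):
    """Malformed or inconsistent user input (e.g. mate-count mismatch)."""
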