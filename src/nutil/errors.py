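"""Exception hierarchy shared across the toolbox."""


class NutilError(Exception):
    """Base class for all toolbox errors."""


class InputError(NutilError):
    """An input file is missing, unreadable, or undecodable."""


class FormatError(NutilError):
    """A file exists but is not in the required format (e.g. striped TIFF)."""


class ParameterError(NutilError):
    """An operation parameter is out of its valid range."""


class ValidationError(NutilError):
    """Cross-file consistency checks failed (pairing, anchoring, labels)."""
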