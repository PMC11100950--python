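"""Exception hierarchy shared across the package."""


class SigsuitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SigsuitError):
    """Invalid parameter value (window lengths, spec fields, combinations)."""


class BoundsError(SigsuitError):
    """An artifact annotation or slice falls outside its record."""


class ModalityError(SigsuitError):
    """An operation was applied to an unsupported signal modality."""


class AlignmentError(SigsuitError):
    """Per-channel segment grids cannot be aligned into joint segments."""


class FormatError(SigsuitError):
    """Malformed input file (EDF header, track table)."""
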