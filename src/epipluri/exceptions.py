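"""Exception hierarchy for epipluri."""


class EpiPluriError(ValueError):
    """Base class for all epipluri errors."""


class BetaParseError(EpiPluriError):
    """A beta-value matrix, annotation or manifest file could not be parsed."""


class MissingValueError(EpiPluriError):
    """An operation hit a missing beta-value it is not allowed to skip."""


class SelectionError(EpiPluriError):
    """Marker selection could not proceed (empty group, no positive margin, ...)."""
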