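"""Exception hierarchy for the abvisc pipeline."""


class AbviscError(Exception):
    """Base class for all abvisc errors."""


class FormatError(AbviscError):
    """Unparseable or malformed input file."""


class EmptyStructureError(AbviscError):
    """No atoms remain after filtering."""


class ParameterizationError(AbviscError):
    """Residue or atom missing from the charge/radius table."""


class AnnotationError(AbviscError):
    """Segment annotation failed (e.g. numbering gaps)."""


class OutOfBoundsError(AbviscError):
    """Atom lies outside the grid extent."""


class ConvergenceError(AbviscError):
    """Iterative solver failed to reach tolerance."""


class ConfigError(AbviscError):
    """Invalid configuration or incompatible settings."""


class DataError(AbviscError):
    """Invalid dataset (empty split, overlapping sets, ...)."""


class DegenerateError(AbviscError):
    """Analysis undefined on the given input (all-zero attributions, ...)."""
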