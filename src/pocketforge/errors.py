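"""Exception hierarchy."""


class PocketforgeError(Exception):
    """Base class for all package errors."""


class ParseError(PocketforgeError):
    """A structure file could not be parsed."""


class ElementError(PocketforgeError):
    """An atom's element is outside the supported vocabulary."""


class DimensionalityError(PocketforgeError):
    """A ligand file carries 2D-only coordinates."""


class EmptyPocketError(PocketforgeError):
    """Pocket extraction produced no atoms."""


class TargetMismatchError(PocketforgeError):
    """Two fingerprints do not belong to the same target/atom order."""


class AlignmentError(PocketforgeError):
    """A per-atom matrix does not align with the structure it describes."""


class AnchorError(PocketforgeError):
    """The requested atom-of-interest is not available."""


class EncoderError(PocketforgeError):
    """The posterior encoder was called on an empty ligand."""


class ConnectivityError(PocketforgeError):
    """A ligand bond graph is disconnected where connectivity is required."""


class UndefinedMetricError(PocketforgeError):
    """A metric is undefined for the given input (e.g. zero valid molecules)."""


class SpecError(PocketforgeError):
    """A synthetic-motif specification is outside the detectable range."""
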