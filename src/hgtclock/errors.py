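"""Exception hierarchy.

All package errors derive from :class:`HGTClockError` so callers can catch
one base class; subclasses distinguish parse-, structure- and
validation-level failures as the I/O contracts require.
"""


class HGTClockError(Exception):
    """Base class for all errors raised by hgtclock."""


class ParseError(HGTClockError):
    """A tree line (or table record) could not be parsed."""


class StructuralError(HGTClockError):
    """Trees or samples violate a structural contract (leaf sets, rooting)."""


class ValidationError(HGTClockError):
    """Numerical validation failed (ultrametricity, negative lengths, ...)."""


class CladeResolutionError(HGTClockError):
    """A clade definition could not be resolved on a tree."""


class MissingTaxonError(CladeResolutionError):
    """A clade references a taxon absent from the tree."""


class UndefinedCrownError(CladeResolutionError):
    """Crown age requested for a single-taxon clade."""


class UndefinedStemError(CladeResolutionError):
    """Total-group (stem) age requested for a clade whose MRCA is the root."""


class SimulationError(HGTClockError):
    """The synthetic-data generator cannot satisfy its configuration."""
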