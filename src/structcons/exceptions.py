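"""Exception hierarchy for structcons."""


class StructconsError(Exception):
    """Base class for all package errors."""


class StructureFormatError(StructconsError):
    """The input file could not be parsed as the named structure format."""


class EmptyStructureError(StructconsError):
    """A parsed structure contains no standard polymer residues."""


class MissingAnnotationError(StructconsError):
    """A required per-residue annotation (e.g. pLDDT) is absent."""


class AlignmentFailureError(StructconsError):
    """No structural alignment with the minimum number of pairs was found."""


class InsufficientPairsError(StructconsError):
    """Fewer than three coordinate pairs were supplied for superposition."""


class UndefinedStatisticError(StructconsError):
    """A statistic is undefined on the given input (empty subset, constant data...)."""


class EmptyProfileError(StructconsError):
    """No member of the orthogroup aligned successfully to the reference."""


class ConfigError(StructconsError):
    """Pipeline configuration failed validation."""
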