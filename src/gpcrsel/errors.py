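"""Exception hierarchy shared across the package."""


class GpcrselError(Exception):
    """Base class for all package-specific errors."""


class StructureFormatError(GpcrselError):
    """A coordinate file could not be parsed under the named standard."""


class ChainLookupError(GpcrselError, KeyError):
    """A requested chain id is absent from the structure."""


class GrnLookupError(GpcrselError, KeyError):
    """A generic residue number could not be resolved in a chain."""


class ConsistencyError(GpcrselError):
    """A mutation would violate a structural invariant (e.g. duplicate GRN)."""


class InsufficientDataError(GpcrselError):
    """Too few atoms/residues to perform the requested computation."""


class DegenerateSegmentError(GpcrselError):
    """A helix segment is geometrically inconsistent with its annotation."""
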