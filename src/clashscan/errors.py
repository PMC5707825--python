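"""Exception hierarchy for clashscan."""


class ClashscanError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(ClashscanError):
    """Malformed PDB input; message carries the 1-based line number."""


class EmptyStructureError(ClashscanError):
    """No usable atoms remain after cleanup."""


class PositionNotFoundError(ClashscanError):
    """A variant position does not resolve to a residue in the structure."""


class IncompleteBackboneError(ClashscanError):
    """Residue lacks one of N, CA, C and cannot host a substitution."""


class NoSideChainError(ClashscanError):
    """Operation requested on glycine, which has no side chain."""


class NoRotamersError(ClashscanError):
    """Rotamer query for a residue type without chi angles (Gly/Ala)."""


class VariantMismatchError(ClashscanError):
    """Variant's stated original residue disagrees with the structure."""


class VariantParseError(ClashscanError):
    """Unparseable variant line; message carries line number and text."""


class LibraryParseError(ClashscanError):
    """Malformed rotamer library row."""


class GeometryError(ClashscanError):
    """Degenerate geometric input (collinear points, bad frame)."""


class UndefinedTorsionError(GeometryError):
    """Torsion requested on collinear points."""


class ResolutionError(ClashscanError):
    """SASA quadrature requested with too few sphere points."""
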