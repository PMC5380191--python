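"""Package exception hierarchy."""


class TorsionfoldError(Exception):
    """Base class for all package-specific errors."""


class PDBFormatError(TorsionfoldError):
    """Malformed or internally inconsistent PDB content."""


class CoefficientFormatError(TorsionfoldError):
    """Malformed torsion-coefficient file."""


class GeometryError(TorsionfoldError):
    """Degenerate geometry (coincident or collinear atoms)."""


class ConvergenceError(TorsionfoldError):
    """An iterative solver failed to reach its tolerance."""
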