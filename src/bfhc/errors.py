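"""Exception hierarchy for the bfhc package."""


class BFHCError(Exception):
    """Base class for all package-specific errors."""


class StructureFormatError(BFHCError):
    """Raised when an XYZ or Gaussian-input file cannot be parsed."""


class BondPerceptionError(BFHCError):
    """Raised when perceived connectivity violates C/H valence rules."""


class RingPerceptionError(BFHCError):
    """Raised when ring perception fails (oversized cycles, no rings where required)."""


class BoundaryError(BFHCError):
    """Raised when the ring-system perimeter is not a single closed walk."""


class BuilderError(BFHCError):
    """Raised for invalid hexagon-fusion specifications."""


class DatasetError(BFHCError):
    """Raised for malformed metadata tables or vocabulary violations."""
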