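"""Exception hierarchy shared across the package."""


class StressmapError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(StressmapError):
    """Malformed PDB text (bad fixed-width columns, empty input, icodes)."""


class ShapeError(StressmapError):
    """Mismatched array shapes / atom counts between related objects."""


class RegionError(StressmapError):
    """Unknown or empty region name in a domain/strand/APR lookup."""


class ConfigError(StressmapError):
    """Invalid pipeline configuration."""


class DegenerateInputError(StressmapError):
    """Input too small or singular for the requested operation."""
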