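"""Exception hierarchy shared across the package."""


class ArspawnerError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ArspawnerError):
    """A file did not conform to the documented on-disk dialect."""


class DimensionMismatchError(ArspawnerError):
    """Two series (or a series and a dataset) disagree on feature dimension."""


class InfeasibleBandError(ArspawnerError):
    """The Sakoe-Chiba window is too narrow to reach the end cell."""


class DegenerateGeometryError(ArspawnerError):
    """A skeletal frame has coincident joints or a vanishing bone vector."""


class DegenerateClassError(ArspawnerError):
    """A class has too few members, or all members are identical."""


class SplitError(ArspawnerError):
    """No admissible split point could be drawn for a pair of series."""
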