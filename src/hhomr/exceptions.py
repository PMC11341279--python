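"""Exception types raised across the package."""


class HhomrError(Exception):
    """Base class for all package-specific errors."""


class CycleError(HhomrError):
    """The disease hierarchy contains a directed cycle."""

    def __init__(self, edge):
        self.edge = edge
        super().__init__(f"disease hierarchy is cyclic; offending edge {edge[0]!r} -> {edge[1]!r}")


class UnknownIdError(HhomrError, KeyError):
    """An identifier was not found in the relevant index."""

    def __init__(self, missing):
        self.missing = tuple(missing) if not isinstance(missing, str) else (missing,)
        super().__init__(f"unknown identifier(s): {', '.join(map(repr, self.missing))}")


class AlignmentError(HhomrError):
    """Two containers that must share an identifier ordering do not."""


class DegenerateBandwidthError(HhomrError):
    """All interaction profiles are zero, so the GIP bandwidth is undefined."""


class CapacityError(HhomrError):
    """A sampling or partitioning request exceeds what the data can provide."""


class ConsistencyError(HhomrError):
    """Labeled pairs overlap or duplicate where they must be disjoint."""


class NumericError(HhomrError):
    """A non-finite value appeared during model computation."""
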