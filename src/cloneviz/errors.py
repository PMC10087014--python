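"""Exception hierarchy shared across the package."""

from __future__ import annotations


class CloneVizError(Exception):
    """Base class for all package-specific errors."""


class StructuralError(CloneVizError):
    """The clone/parent structure itself is broken (cycle, shape mismatch,
    dangling reference) -- raised before any of the four table rules is
    even considered."""

    def __init__(self, message: str, cycle: tuple[str, ...] | None = None):
        super().__init__(message)
        self.cycle = cycle


class ValidationError(CloneVizError):
    """A CCF table violates one of the validity rules; carries the full
    structured report."""

    def __init__(self, report):
        lines = "; ".join(v.message for v in report.violations)
        super().__init__(f"invalid clonal evolution: {lines}")
        self.report = report


class CloneLookupError(CloneVizError, KeyError):
    """An operation referenced a clone label that does not exist."""


class FractionScaleError(CloneVizError):
    """All CCF values are <= 1: the table looks like fractions, but percent
    values (0-100) are required.  Rescale explicitly instead of relying on
    silent conversion."""


class CapacityError(CloneVizError):
    """A hard capacity limit was exceeded (e.g. the 25-founder palette)."""


class PermutationCapError(CloneVizError):
    """The filtered candidate space of the tree explorer exceeds the
    permutation cap; no partial enumeration is returned."""

    def __init__(self, size: int, cap: int):
        super().__init__(
            f"candidate parental-relation space of size {size} exceeds the "
            f"maximum of {cap} permutations; aborting without partial results"
        )
        self.size = size
        self.cap = cap


class ParseError(CloneVizError):
    """A CCF table file could not be parsed."""


class SimulationSpecError(CloneVizError):
    """A simulation specification is internally inconsistent."""


class UsageError(CloneVizError):
    """An operation was invoked with arguments outside its contract."""
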