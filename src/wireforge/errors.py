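"""Exception hierarchy for the wireforge framework."""


class WireforgeError(Exception):
    """Base class for all framework errors."""


class TriangulationError(WireforgeError):
    """The preserved geometry cannot be closed into a triangulated surface."""


class InfeasibleStartError(WireforgeError):
    """The initial triangulated state violates a design constraint."""


class RegionConflictError(WireforgeError):
    """Preserved geometry intersects an excluded region."""


class ZeroLengthEdgeError(WireforgeError):
    """An edge of zero Euclidean length cannot carry nucleotides."""


class PreservedGeometryError(WireforgeError):
    """A grammar rule attempted to modify preserved vertices or edges."""


class MeshInvalidError(WireforgeError):
    """A grammar rule would produce a non-manifold or degenerate mesh."""


class FlipBlockedError(WireforgeError):
    """Edge flip is not applicable (opposite edge exists or degenerate result)."""


class SpatialConstraintError(WireforgeError):
    """A geometric move violates a spatial restriction (box or excluded region)."""


class ExhaustedRetriesError(WireforgeError):
    """No feasible candidate was found within the retry budget."""


class CustomConstraintError(WireforgeError):
    """A user-supplied constraint predicate raised an exception."""


class ZeroVolumeError(WireforgeError):
    """Porosity is undefined for a state without DNA material."""


class DuplicateNameError(WireforgeError):
    """An objective with this name is already registered."""


class NonFiniteObjectiveError(WireforgeError):
    """An objective evaluated to NaN or infinity."""


class NonFiniteEnergyError(WireforgeError):
    """Metropolis comparison received a non-finite energy."""


class ObjectiveCountError(WireforgeError):
    """Multi-objective annealing is validated only for 2 or 3 objectives."""


class ArityMismatchError(WireforgeError):
    """Objective vectors of different lengths cannot be compared."""


class SchemaError(WireforgeError):
    """A problem configuration failed validation."""

    def __init__(self, key: str, message: str):
        self.key = key
        super().__init__(f"{key}: {message}")


class UnknownObjectiveError(WireforgeError):
    """Configuration referenced an objective name that is not registered."""


class UnsupportedFormatError(WireforgeError):
    """Requested mesh export/import format is not supported."""
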