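"""Exception types shared across the package."""


class AirwaylossError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(AirwaylossError, ValueError):
    """An argument violates a documented precondition."""


class InvalidSpecError(InvalidInputError):
    """A generator specification is self-inconsistent or out of range."""


class EmptySectionError(AirwaylossError):
    """A slicing plane does not intersect the surface mesh."""


class TopologyError(AirwaylossError):
    """A mesh/plane intersection produced an open (non-closed) loop."""


class EmptyWindowError(AirwaylossError):
    """Time averaging discarded every snapshot."""


class ConservationError(AirwaylossError):
    """Plane flowrates disagree beyond the mass-conservation tolerance."""


class UnknownUnitError(AirwaylossError, ValueError):
    """A unit string is not one of the supported resistance units."""
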