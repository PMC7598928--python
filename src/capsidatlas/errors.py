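"""Named exceptions shared across the package."""


class CapsidAtlasError(Exception):
    """Base class for all package errors."""


class MissingChainError(CapsidAtlasError):
    """Requested chain is absent from the structure file."""


class EmptySelectionError(CapsidAtlasError):
    """Atom selection matched nothing."""


class StericClashError(CapsidAtlasError):
    """Two atoms are closer than the sum of their van der Waals radii."""


class UnitMismatchError(CapsidAtlasError):
    """Two configurations do not share the same rigid units / atom ordering."""


class ConstraintViolationError(CapsidAtlasError):
    """A witness configuration does not satisfy the constraints it claims."""


class UnknownInteractionError(CapsidAtlasError):
    """An interaction id does not exist in the system."""


class UnknownTypeError(CapsidAtlasError):
    """An interface-type label does not exist."""


class ChartError(CapsidAtlasError):
    """No valid Cayley parameter completion could be constructed."""


class FixtureError(CapsidAtlasError):
    """Rejection sampling for a synthetic fixture failed."""


class DegenerateDataError(CapsidAtlasError):
    """A generated dataset collapsed to a single class or is otherwise unusable."""
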