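"""Exception types shared across the reconstruction pipeline."""


class StentRecError(Exception):
    """Base class for all pipeline errors."""


class InvalidParameterError(StentRecError, ValueError):
    """A tunable argument is outside its admissible range."""


class InvalidInputError(StentRecError, ValueError):
    """Input data violate a structural precondition."""


class OutOfRangeError(StentRecError, ValueError):
    """A station or coordinate falls outside the supported range."""


class InsufficientInputError(StentRecError, ValueError):
    """Too few inputs to perform the operation."""


class InvalidContourError(StentRecError, ValueError):
    """A contour is degenerate or self-intersecting."""


class MissingReferenceError(StentRecError, ValueError):
    """No marker available to fix absolute orientation."""


class CannotBridgeError(StentRecError, ValueError):
    """A shadow gap is too wide to bridge without a template."""


class TemplateMismatchWarning(UserWarning):
    """Observed strut layout disagrees with the stent template."""


class InvalidSpecError(StentRecError, ValueError):
    """A phantom specification is geometrically infeasible."""


class EditError(StentRecError, ValueError):
    """A manual wireframe edit would break a graph invariant."""
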