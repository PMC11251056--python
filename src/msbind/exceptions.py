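"""Exception hierarchy shared across the package."""


class MsbindError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(MsbindError, ValueError):
    """A numeric or structural precondition on user input is violated."""


class ShapeError(MsbindError, ValueError):
    """Dimension mismatch between model and data (e.g. n_max vs F columns)."""


class IdentifiabilityError(MsbindError, ValueError):
    """Fewer distinct titration concentrations than free parameters."""


class ConfigurationError(MsbindError, ValueError):
    """An analysis setting is inconsistent (e.g. assignment tolerance too wide)."""


class AmbiguousAssignmentError(MsbindError, ValueError):
    """A deconvolved peak is exactly equidistant between two candidate species."""


class UndefinedFractionError(MsbindError, ZeroDivisionError):
    """Mole fractions requested from an all-zero intensity set."""


class EmptySelectionError(MsbindError, KeyError):
    """A stoichiometry selector matched no cell of the table."""


class AlignmentError(MsbindError, ValueError):
    """Replicate time grids differ where exact alignment is required."""


class LookupFailure(MsbindError, KeyError):
    """A chain/residue/atom selector did not resolve in a structure."""


class SchemaError(MsbindError, ValueError):
    """A CSV/JSON input does not match the declared schema."""
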