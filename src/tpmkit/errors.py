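"""Exception hierarchy.

All package-specific failures derive from :class:`TpmkitError` so callers
(and the CLI) can distinguish bad input (subclasses of :class:`InputError`)
from numerical/geometric failures (subclasses of :class:`ComputationError`).
"""


class TpmkitError(Exception):
    """Base class for all tpmkit errors."""


class InputError(TpmkitError):
    """Invalid or unusable input (file, selection, parameterization)."""


class ComputationError(TpmkitError):
    """A computation could not be carried out on otherwise valid input."""


# --- input-side errors -------------------------------------------------------

class FormatError(InputError):
    """A file could not be parsed, or violates format constraints."""


class CoordinateOverflowError(FormatError):
    """Coordinates exceed the fixed-column PDB field width."""


class SelectionError(InputError):
    """A selection did not resolve to any atoms."""


class ParameterError(InputError):
    """An argument is out of its documented range."""


class WindowError(InputError):
    """A residue/frame window is empty or too short."""


class AlignmentError(InputError):
    """Residue indices of paired helices (or mapped windows) do not align."""


class LengthError(InputError):
    """A sequence is too short for the span it must cover."""


class TrajectoryError(InputError):
    """Multi-model topology mismatch or too few frames."""


class InsufficientInputError(InputError):
    """Fewer points/atoms than the operation's minimum."""


class DilutionError(InputError):
    """Requested specific activity is not reachable by cold dilution."""


class ComparisonError(InputError):
    """Two datasets do not overlap enough to compare."""


# --- computation-side errors -------------------------------------------------

class DegenerateGeometryError(ComputationError):
    """Collinear or otherwise degenerate coordinates."""


class GeometryError(ComputationError):
    """Builder parameters imply non-physical geometry."""


class ClashError(ComputationError):
    """Atoms closer than the allowed hard-sphere minimum."""


class FitError(ComputationError):
    """A nonlinear fit failed to converge or found nothing to fit."""


class NormalizationError(ComputationError):
    """Baselines indistinguishable; melt curve cannot be normalized."""
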