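"""Exception hierarchy.

Every error raised by the package derives from :class:`PuckerfitError`, so
callers can catch one base class at workflow boundaries.
"""


class PuckerfitError(Exception):
    """Base class for all package errors."""


# --- geometry ---------------------------------------------------------------

class CollinearPoints(PuckerfitError):
    """Three consecutive points of a dihedral are (near-)collinear."""


class ZeroAmplitude(PuckerfitError):
    """Pseudorotation phase is undefined for a planar ring."""


class EmbeddingNotConverged(PuckerfitError):
    """Ring embedding failed to reach the target pucker within tolerance."""


# --- I/O --------------------------------------------------------------------

class ParseError(PuckerfitError):
    """A file could not be parsed; the message carries the line number."""


class RingNotFound(PuckerfitError):
    """No unique 5-membered ring with exactly one oxygen was found."""


class ChargeMismatch(PuckerfitError):
    """Per-atom charges do not sum to the declared net charge."""


class InconsistentFrame(PuckerfitError):
    """A trajectory frame has the wrong atom count or is malformed."""


class UnsupportedPhase(PuckerfitError):
    """A dihedral phase outside {0, 180} degrees was encountered."""


# --- energy -----------------------------------------------------------------

class MissingParameter(PuckerfitError):
    """A required force-field term is absent; message names the type key."""


class ZeroDistance(PuckerfitError):
    """Two nonbonded atoms coincide."""


class InvalidPeriodicity(PuckerfitError):
    """Dihedral periodicity outside {1, 2, 3}."""


class ShapeMismatch(PuckerfitError):
    """Coordinate arrays disagree in shape."""


# --- fitting ----------------------------------------------------------------

class NoAdjustableTerms(PuckerfitError):
    """The fit problem exposes no adjustable torsion class."""


class RankDeficient(PuckerfitError):
    """Design matrix is rank deficient; message lists null-space keys."""


class DimensionMismatch(PuckerfitError):
    """Design matrix and response disagree in length."""


class KeyMismatch(PuckerfitError):
    """Two fit results do not share the same set of torsion keys."""


class NotConverged(PuckerfitError):
    """Iterative refinement exhausted its outer-iteration budget."""


class SingularSystem(PuckerfitError):
    """Charge-fit normal equations are singular (degenerate geometry)."""


class PointOnAtom(PuckerfitError):
    """An ESP grid point coincides with an atomic position."""


class Mismatch(PuckerfitError):
    """Two charge sets or grids are structurally incompatible."""


# --- analysis ---------------------------------------------------------------

class EmptySeries(PuckerfitError):
    """An operation that needs at least one frame received none."""


class BadBinWidth(PuckerfitError):
    """Histogram bin width does not divide 360 degrees."""


class LengthMismatch(PuckerfitError):
    """Paired energy vectors differ in length."""


class DegenerateX(PuckerfitError):
    """Through-origin regression needs a non-degenerate abscissa."""
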