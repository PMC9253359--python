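"""Exception hierarchy for the curlikin pipeline."""


class CurlikinError(Exception):
    """Base class for all curlikin-specific errors."""


class GridMismatchError(CurlikinError):
    """Two traces that must share a time grid do not."""


class NoTransitionError(CurlikinError):
    """A ThT trace has no detectable sigmoidal transition (flat trace)."""


class FitError(CurlikinError):
    """A least-squares fit failed to converge or is otherwise unusable."""


class SaturationError(CurlikinError):
    """Free-protein abundance is zero: the abundance ratio R is undefined."""


class MassBalanceError(CurlikinError):
    """Inputs violate the 1:1 binding mass balance (implied [P2]eq <= 0)."""


class CalibrationError(CurlikinError):
    """A calibration (ionization response or CCS) cannot be fitted."""


class SequenceError(CurlikinError):
    """A protein sequence contains characters outside the amino-acid alphabet."""
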