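"""Typed errors raised across the package.

Statistics that are undefined on a given input raise instead of returning
NaN, so that resampling drivers can count or redraw degenerate resamples
explicitly.
"""


class ConcordxError(Exception):
    """Base class for all package errors."""


class InvalidInputError(ConcordxError, ValueError):
    """Input fails a precondition (wrong shape, non-finite values, bad n)."""


class UndefinedStatisticError(ConcordxError):
    """The statistic is undefined on this input (e.g. zero valid pairs)."""


class UnsupportedTieStructureError(ConcordxError):
    """Tie structure has no exact null (both vectors tied); use permutations."""


class CalibrationError(ConcordxError):
    """Threshold/kernel calibration failed (degenerate or non-monotone fit)."""


class DegenerateModelError(ConcordxError):
    """A fitted noise model is degenerate (e.g. zero scale)."""
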