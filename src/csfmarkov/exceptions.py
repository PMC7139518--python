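"""Exception hierarchy.

All domain errors derive from :class:`CSFMarkovError` so callers can catch
package failures with a single except clause; subclasses also derive from
the closest builtin (``ValueError``/``KeyError``) for idiomatic handling.
"""


class CSFMarkovError(Exception):
    """Base class for all errors raised by csfmarkov."""


class RateBoundsError(CSFMarkovError, ValueError):
    """A transition rate lies outside [0, 1]."""


class InfeasibleRatesError(CSFMarkovError, ValueError):
    """Rates violate a feasibility constraint (e.g. alpha1 + beta1 > 1)."""


class DegenerateCompartmentError(CSFMarkovError, ValueError):
    """A compartment carries zero mass, so within-compartment fractions
    are undefined."""


class MissingDataError(CSFMarkovError, ValueError):
    """A required field (e.g. total cell counts) is absent."""


class CohortParseError(CSFMarkovError, ValueError):
    """A cohort or rate-table file failed validation; the message carries
    the offending row."""


class NonConvergenceError(CSFMarkovError, RuntimeError):
    """The optimiser failed from every start point.

    Attributes
    ----------
    diagnostics : list of dict
        Per-start solver status, message and final objective.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class UnknownRatesError(CSFMarkovError, KeyError):
    """Lookup of a (cell_type, group) pair not present in a rate table."""
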