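"""Exception hierarchy.

All package errors derive from :class:`ConnManovaError` so callers can catch
one base class; most also derive from ``ValueError`` because they signal
invalid inputs rather than programming faults.
"""


class ConnManovaError(Exception):
    """Base class for all errors raised by connmanova."""


class SchemaError(ConnManovaError, ValueError):
    """A table is missing required columns or is otherwise malformed."""


class ParseError(ConnManovaError, ValueError):
    """A cell could not be parsed into the required dtype."""


class IntegrityError(ConnManovaError, ValueError):
    """A uniqueness or coding invariant is violated (e.g. duplicate ids)."""


class AlignmentError(ConnManovaError, ValueError):
    """Subjects or parcels do not line up between two tables."""


class CollinearityError(ConnManovaError, ValueError):
    """A design matrix is rank deficient; names the dependent columns."""


class RankError(ConnManovaError, ValueError):
    """A matrix required to be nonsingular is (numerically) singular."""


class DegenerateDataError(ConnManovaError, ValueError):
    """Data degenerate for the requested statistic (zero variance, E singular)."""


class InsufficientDFError(ConnManovaError, ValueError):
    """Not enough error degrees of freedom for the requested test."""
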