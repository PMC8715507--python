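"""Exception hierarchy for :mod:`jchi`."""


class JchiError(Exception):
    """Base class for all package errors."""


class InvalidInputError(JchiError, ValueError):
    """A value violates a precondition (non-finite, wrong sign, ...)."""


class SchemaError(JchiError, ValueError):
    """A delimited-text table does not match the expected schema."""


class MissingCouplingError(JchiError, KeyError):
    """A requested coupling has no Karplus coefficients or topology entry."""


class RankDeficientError(JchiError, ValueError):
    """The least-squares design matrix is rank deficient."""

    def __init__(self, message: str, deficient_columns=()):
        super().__init__(message)
        self.deficient_columns = tuple(deficient_columns)


class DegenerateProfileError(JchiError, ValueError):
    """An rmsd profile is flat and carries no angular information."""


class DegenerateMeanError(JchiError, ValueError):
    """The circular mean is undefined (zero resultant vector)."""


class FixtureIntegrityError(JchiError, RuntimeError):
    """Packaged reference tables failed their integrity check."""
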