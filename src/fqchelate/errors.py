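"""Exception hierarchy shared across the pipeline stages."""


class FQChelateError(Exception):
    """Base class for all package-specific errors."""


class DomainError(FQChelateError, ValueError):
    """An input is outside the mathematical domain of an operation."""


class NoSolutionError(FQChelateError, ValueError):
    """A root-finding problem has no solution on the requested branch."""


class SelectionError(FQChelateError, ValueError):
    """A data-selection rule yielded too few points."""


class FitError(FQChelateError, ValueError):
    """A regression could not be performed or gave an unphysical result."""


class ParseError(FQChelateError, ValueError):
    """A chemical structure or file could not be parsed."""


class SubstructureError(FQChelateError, ValueError):
    """A required substructure (e.g. the chelation pocket) was not found."""


class GeometryError(FQChelateError, ValueError):
    """A constructed 3D geometry is unusable (clashes, impossible distances)."""


class StoichiometryError(FQChelateError, ValueError):
    """A reaction does not balance atoms or charge."""


class LedgerError(FQChelateError, ValueError):
    """An energy ledger is missing a required component."""


class AssemblyError(FQChelateError, ValueError):
    """A dataset-assembly rule failed (missing descriptor, missing arm)."""


class AmbiguityError(FQChelateError, ValueError):
    """A selection rule left a tie it cannot break."""


class StudyError(FQChelateError, RuntimeError):
    """Too many per-subject extractions failed in a simulated study."""


class AdapterError(FQChelateError, RuntimeError):
    """An external engine adapter (force field, QM) raised during scoring."""
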