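"""Exception hierarchy.

Everything raised on purpose derives from :class:`ChromlipError`, so callers
can catch one type at a pipeline boundary while tests assert on the precise
subclass.
"""


class ChromlipError(Exception):
    """Base class for all package errors."""


class StructureParseError(ChromlipError):
    """A SMILES string could not be parsed into a molecule."""


class ConfigurationError(ChromlipError):
    """Unknown convention, adduct, element or configuration key."""


class UnsupportedEnvironmentError(ChromlipError):
    """A polar atom has no entry in the TPSA fragment table.

    Raised instead of silently contributing zero area.
    """


class InvalidSpotError(ChromlipError):
    """A TLC spot did not migrate or ran with the solvent front (Rf in {0, 1})."""


class InsufficientDataError(ChromlipError):
    """Too few points for the requested fit or extrapolation."""


class DegenerateDesignError(ChromlipError):
    """The regressor has zero variance; the fit is undefined."""


class MissingDescriptorError(ChromlipError):
    """A rule evaluation needs a descriptor that was not supplied."""


class InputError(ChromlipError):
    """Malformed input table (bad column, conflicting roles, duplicate ids...)."""


class ParameterError(ChromlipError):
    """Simulation parameters are infeasible or inconsistent."""
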