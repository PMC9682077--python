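"""Exception hierarchy for the catabarrier package."""


class CatabarrierError(Exception):
    """Base class for all package-specific errors."""


class RegimeError(CatabarrierError):
    """The parameter set does not have the bistable (3 fixed point) structure."""


class RootNotFound(CatabarrierError):
    """A bracketed root search failed to locate a solution."""


class UnknownDrug(CatabarrierError):
    """A regimen references a drug with no (or an incomplete) registry record."""


class UnknownReceptor(CatabarrierError):
    """A receptor profile entry is outside the supported receptor set."""


class DomainError(CatabarrierError):
    """A closed-form expression was evaluated outside its numerical domain."""


class ConfigError(CatabarrierError):
    """Invalid configuration (marginals, correlation matrix, paths...)."""


class DegenerateGroup(CatabarrierError):
    """Effect-size computation on groups with zero spread."""


class DegenerateInput(CatabarrierError):
    """Correlation requested against a constant variable."""


class DegenerateMap(CatabarrierError):
    """The two mean barriers coincide; no affine severity map exists."""


class CalibrationFailure(CatabarrierError):
    """No bistable personalization parameters satisfy the bounds."""
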