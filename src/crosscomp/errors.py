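"""Exception hierarchy for the toolkit.

Every error raised on purpose derives from :class:`CrossCompError`, so
callers can catch toolkit failures without swallowing programming errors.
"""


class CrossCompError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(CrossCompError):
    """A domain object violates one of its structural invariants."""


class ParameterError(CrossCompError, ValueError):
    """A parameter is outside its valid range or inconsistent with others."""


class ConfigurationError(CrossCompError):
    """Required configuration (gene index, universe, ...) is missing or empty."""


class InsufficientOverlapError(CrossCompError):
    """Two profiles share fewer jointly observed contrasts than required."""


class DegenerateProfileError(CrossCompError):
    """A profile has (numerically) zero norm on the evaluated contrasts."""


class EmptyProfileError(CrossCompError):
    """A profile has no observed values at all."""


class ParseError(CrossCompError):
    """An input table or file does not conform to its expected layout."""


class DefinitionError(CrossCompError):
    """A contrast definition is malformed or references unknown data."""


class DomainError(CrossCompError):
    """Input values are outside the mathematical domain of an operation."""


class FitError(CrossCompError):
    """A curve fit cannot be performed (e.g. too few points)."""


class AssemblyError(CrossCompError):
    """Compendium assembly failed (e.g. duplicate contrast identifiers)."""


class AnnotationError(CrossCompError):
    """Condition-property annotation is inconsistent (type mismatch, ...)."""


class RegistryError(CrossCompError):
    """A property or ontology term is unknown to its registry."""


class SetLookupError(CrossCompError, KeyError):
    """A named gene set does not exist."""


class CreationError(CrossCompError):
    """Module creation produced an empty or unusable result."""


class DegenerateResultError(CrossCompError):
    """An editing operation emptied a module in one direction."""
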