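"""Exception hierarchy shared across the package."""


class CMKGError(Exception):
    """Base class for all package errors."""


class FormatError(CMKGError):
    """A file does not conform to the expected tabular layout."""


class IntegrityError(CMKGError):
    """Data violates a store invariant (duplicate ids, dangling refs, ...)."""


class ConfigurationError(CMKGError):
    """Invalid or inconsistent configuration values."""


class EntityLookupError(CMKGError, KeyError):
    """An entity id does not resolve in the store."""


class ShapeError(CMKGError):
    """Vector dimensions do not match."""


class ConstraintError(CMKGError):
    """A model constraint is violated (e.g. non-unit rotation modulus)."""


class TrainingError(CMKGError):
    """Embedding optimisation failed (e.g. non-finite loss)."""


class RuleParseError(CMKGError):
    """A rule file line could not be parsed."""
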