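"""Exception hierarchy shared across the package."""


class MetexpandError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MetexpandError):
    """A structure document could not be parsed (syntax level)."""


class ChemistryError(MetexpandError):
    """A structure parsed but is chemically impossible (e.g. valence)."""


class RuleLoadError(MetexpandError):
    """A reaction-rule document violates the rule schema."""

    def __init__(self, message: str, rule_id: str | None = None, field: str | None = None):
        self.rule_id = rule_id
        self.field = field
        prefix = f"rule {rule_id!r}" + (f", field {field!r}" if field else "") + ": " if rule_id else ""
        super().__init__(prefix + message)


class ConfigError(MetexpandError):
    """An out-of-guard or inconsistent run configuration."""


class ConsistencyError(MetexpandError):
    """Stored data no longer agrees with recomputation (e.g. a rule that
    does not re-match the substrate of a recorded reaction)."""


class ValidationError(MetexpandError):
    """Invalid user-supplied value (negative counts etc.)."""
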