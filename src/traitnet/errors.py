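"""Exception hierarchy shared across the package."""


class TraitnetError(Exception):
    """Base class for all package errors."""


class SchemaError(TraitnetError):
    """A required column or field is missing or mistyped."""


class ParseError(TraitnetError):
    """Malformed input file (bad cell, bad Newick, ...)."""


class ValidationError(TraitnetError):
    """Input parses but violates an invariant."""


class ConfigError(TraitnetError):
    """Inconsistent generator or pipeline configuration."""
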