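class OxibalanceError(Exception):
    """Base class for pipeline errors."""


class ConfigurationError(OxibalanceError):
    """Invalid configuration value; the message names the offending field."""


class SchemaError(OxibalanceError):
    """Input table does not match the declared schema."""


class ModelError(OxibalanceError):
    """A statistical model could not be fitted (singular design, empty cell, ...)."""
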