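"""Exception hierarchy shared across the package."""


class MirkitError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MirkitError, ValueError):
    """Invalid input data (bad alphabet, malformed interval, bad counts...)."""


class SchemaError(MirkitError, ValueError):
    """A tabular input does not match the expected column schema."""
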