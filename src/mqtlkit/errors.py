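"""Exception types shared across the toolkit."""


class MqtlError(Exception):
    """Base class for all toolkit errors."""


class InvalidInputError(MqtlError, ValueError):
    """An argument violates a documented precondition."""


class SchemaError(MqtlError, ValueError):
    """A tabular input is missing mandatory columns or is malformed."""
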