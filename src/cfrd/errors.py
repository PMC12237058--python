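"""Exception hierarchy for the cfrd package."""


class CfrdError(Exception):
    """Base class for all cfrd errors."""


class SchemaError(CfrdError):
    """An input table does not have the expected columns."""


class ValidationError(CfrdError):
    """An input violates a domain invariant (values, ordering, duplicates)."""
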