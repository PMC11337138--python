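"""Exception hierarchy shared across the ETL stages."""


class CaretlError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(CaretlError):
    """A generator or pipeline configuration field is invalid."""


class CapacityError(CaretlError):
    """More defects were requested than candidate records exist."""


class ParseError(CaretlError):
    """A source document is not well-formed XML."""


class SchemaError(CaretlError):
    """A source document does not conform to the documented export schema."""


class IntegrityError(CaretlError):
    """Referential integrity or uniqueness violated (staging or vocabulary)."""


class InputError(CaretlError):
    """A syntactically invalid input value (e.g. a malformed drug code)."""


class SchemaExistsError(CaretlError):
    """The relational schema already exists in the target database."""


class OrderingError(CaretlError):
    """Tables were loaded out of dependency order (vocabulary must come first)."""
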