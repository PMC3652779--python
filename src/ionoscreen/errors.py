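"""Exception hierarchy shared across the pipeline stages."""


class IonoscreenError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(IonoscreenError):
    """An input table is missing a required column."""


class ParseError(IonoscreenError):
    """A cell could not be parsed; the message carries the row number."""


class ValidationError(IonoscreenError):
    """A record violates a domain invariant (bad well id, od600 <= 0, ...)."""


class FormatError(IonoscreenError):
    """A file does not match any recognized external format layout."""


class ConfigError(IonoscreenError):
    """A configuration value is out of range or unknown."""


class OntologyError(IonoscreenError):
    """The ontology graph violates its invariants (e.g. contains a cycle)."""
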