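"""Exception hierarchy for the pipeline."""


class BreathVocError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(BreathVocError):
    """A table is missing a mandatory column or has an inconsistent layout."""


class ParseError(BreathVocError):
    """A cell could not be parsed; carries row/column context in the message."""


class ValidationError(BreathVocError):
    """Input data violate a contract (duplicate subject, negative age, ...)."""


class FitError(BreathVocError):
    """Numerical failure in model fitting (divergence, non-convergence)."""
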