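"""Exception hierarchy for the cafescreen engine."""


class CafeScreenError(Exception):
    """Base class for all cafescreen errors."""


class FixtureFormatError(CafeScreenError):
    """A packaged or user-supplied fixture is malformed; the message names the field."""


class CapacityError(CafeScreenError):
    """A sampling request exceeds the number of eligible menu items."""


class ProtocolOrderError(CafeScreenError):
    """A phase was submitted out of the legal phase order."""


class ResponseReferenceError(CafeScreenError):
    """A response refers to an unknown item, table, or customer."""


class IncompleteInputError(CafeScreenError):
    """Responses were not supplied for a level the session continued into."""


class FormMismatchError(CafeScreenError):
    """A screener response does not cover the form's items exactly once."""


class PointRangeError(CafeScreenError):
    """A point value lies outside its permitted range."""


class DegenerateInputError(CafeScreenError):
    """A statistic's input is degenerate (e.g. zero variance)."""


class SampleSizeError(CafeScreenError):
    """A statistical routine received fewer observations than it requires."""


class CohortSpecError(CafeScreenError):
    """A cohort specification is invalid (e.g. negative SD)."""


class SchemaError(CafeScreenError):
    """A tabular input is missing required columns; the message names them."""
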