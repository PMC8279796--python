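"""Exception hierarchy for the query engine."""


class TQLError(Exception):
    """Base class for all errors raised by this package."""


class TQLSyntaxError(TQLError):
    """Lexical or grammatical error in a TQL program.

    Carries the 1-based ``line`` and ``column`` where the problem was found.
    """

    def __init__(self, message: str, line: int = 0, column: int = 0):
        self.line = line
        self.column = column
        super().__init__(f"{message} (line {line}, column {column})" if line else message)


class EvalError(TQLError):
    """Raised when a query cannot be evaluated against a patient record."""


class DataLoadError(TQLError):
    """Raised for malformed or inconsistent input data (OMOP CSVs, shards)."""


class OntologyError(TQLError):
    """Raised for malformed ontology inputs (e.g. a cyclic parent-child graph)."""
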