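"""Exception hierarchy for template-driven ontology population."""


class OntopopError(Exception):
    """Base class for all errors raised by this package."""


class DialectError(OntopopError):
    """An ontology document failed to parse in the named dialect."""


class UnknownDialectError(OntopopError):
    """A dialect name outside {obo, turtle, rdfxml} was requested."""


class UnknownTermError(OntopopError):
    """A range specification names a root absent from the snapshot."""

    def __init__(self, iri: str):
        super().__init__(f"unknown term: {iri}")
        self.iri = iri


class PatternSyntaxError(OntopopError):
    """Pattern script text is not valid in the supported OPPL subset."""

    def __init__(self, message: str, line: int, column: int):
        super().__init__(f"{message} (line {line}, column {column})")
        self.line = line
        self.column = column


class UnsupportedConstructError(OntopopError):
    """A valid OPPL 2 construct outside the implemented subset was used."""

    def __init__(self, construct: str, line: int = 0, column: int = 0):
        super().__init__(
            f"unsupported OPPL construct: {construct}"
            + (f" (line {line}, column {column})" if line else "")
        )
        self.construct = construct


class BindingError(OntopopError):
    """A pattern action references an input variable with no binding."""

    def __init__(self, variable: str, row: int | None = None):
        at = f" at row {row}" if row is not None else ""
        super().__init__(f"unbound pattern variable {variable}{at}")
        self.variable = variable
        self.row = row


class MintOverflowError(OntopopError):
    """The identifier counter exceeded the zero-padded numeric width."""


class ConfigurationError(OntopopError):
    """A workflow configuration is structurally invalid."""


class UnsupportedVersionError(ConfigurationError):
    """A stored workflow declares a version this build cannot read."""


class WorkbookFormatError(OntopopError):
    """A spreadsheet file could not be read as a template workbook."""
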