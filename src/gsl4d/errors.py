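"""Exception hierarchy for gsl4d."""


class GSLError(Exception):
    """Base class for all gsl4d errors."""


class GSLParseError(GSLError):
    """A shorthand species or ion name could not be parsed.

    Carries the offending token and, where known, the character position.
    """

    def __init__(self, message: str, token: str = "", position: int | None = None):
        super().__init__(message)
        self.token = token
        self.position = position


class RegistryError(GSLError):
    """Unknown GSL class or malformed registry resource."""


class LibrarySchemaError(GSLError):
    """A library file violates the documented TSV/JSON schema."""

    def __init__(self, message: str, rows: list | None = None):
        super().__init__(message)
        self.rows = rows or []
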