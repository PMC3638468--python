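"""Exception hierarchy shared across phenosim modules."""


class PhenosimError(Exception):
    """Base class for all phenosim errors."""


class ParseError(PhenosimError):
    """Malformed input file; message names the offending line where known."""


class ValidationError(PhenosimError):
    """Structurally invalid data (e.g. a cycle in a graph that must be acyclic)."""


class UnknownTermError(PhenosimError, KeyError):
    """A term id was looked up that does not exist in the ontology."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return self.args[0] if self.args else ""
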