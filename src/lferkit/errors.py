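"""Exception hierarchy for lferkit."""


class LFERKitError(Exception):
    """Base class for all lferkit errors."""


class FormulaParseError(LFERKitError):
    """Malformed molecular-formula string; carries the offending position."""

    def __init__(self, text: str, position: int, message: str) -> None:
        self.text = text
        self.position = position
        super().__init__(f"cannot parse formula {text!r} at position {position}: {message}")


class UnsupportedElement(LFERKitError):
    """Element outside the nine-element scope (C, H, O, N, S, F, Cl, Br, I)."""

    def __init__(self, symbol: str) -> None:
        self.symbol = symbol
        super().__init__(f"unsupported element {symbol!r}: only C, H, O, N, S, F, Cl, Br, I are covered")


class StructureError(LFERKitError):
    """Structure cannot be parsed or is out of scope (charged/radical species)."""


class TableError(LFERKitError):
    """Compound-table schema or content violation."""


class MissingDescriptor(LFERKitError):
    """A required descriptor value is unavailable for a compound."""

    def __init__(self, compound_id: str, descriptor: str = "HM_HBD") -> None:
        self.compound_id = compound_id
        self.descriptor = descriptor
        super().__init__(f"no {descriptor} value available for compound {compound_id!r}")


class CollinearDescriptors(LFERKitError):
    """Descriptor matrix is rank deficient; lists the offending columns."""

    def __init__(self, columns: list[str]) -> None:
        self.columns = list(columns)
        super().__init__(f"descriptor matrix is rank deficient; collinear columns: {', '.join(self.columns)}")


class BasisMismatch(LFERKitError):
    """A descriptor vector's logP basis does not match the model's basis."""

    def __init__(self, expected: str, got: str) -> None:
        self.expected = expected
        self.got = got
        super().__init__(f"model expects logP basis {expected!r} but the descriptor vector carries {got!r}")


class ModelFormatError(LFERKitError):
    """Serialized model text is malformed or has an unknown schema version."""
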