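"""Exception types shared across the package."""


class MinidockError(Exception):
    """Base class for all package errors."""


class InputError(MinidockError):
    """Malformed or inconsistent user input (bad coordinates, length mismatches)."""


class ParseError(MinidockError):
    """A file could not be parsed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DegenerateGeometryError(MinidockError):
    """Matched point set is too close to collinear to define an orientation."""


class OutOfGridError(MinidockError):
    """A query point falls outside the scored lattice region."""


class UndockableMoleculeError(MinidockError):
    """Molecule lacks a rigid component large enough for matching."""


class MetricError(MinidockError):
    """An evaluation metric was asked of an input it is undefined for."""
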