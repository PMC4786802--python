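"""Exception hierarchy shared across the pipeline stages."""


class ClampscreenError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(ClampscreenError):
    """An ATOM/HETATM/MODEL record could not be parsed; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class TopologyError(ClampscreenError):
    """Models of a multi-model file (or frames of a trajectory) disagree in atom content."""


class SelectionError(ClampscreenError):
    """A selection expression is malformed or selects nothing where atoms are required."""


class FitError(ClampscreenError):
    """Superposition impossible: too few fit atoms or degenerate geometry."""


class ParameterError(ClampscreenError):
    """A numeric parameter is out of its admissible range."""


class WindowError(ClampscreenError):
    """An analysis window lies outside the trajectory."""


class FormulaError(ClampscreenError):
    """A molecular formula contains an unknown element symbol."""


class LibraryError(ClampscreenError):
    """A compound library file yielded no parsable record."""


class SpecError(ClampscreenError):
    """A synthetic-data specification is internally contradictory or infeasible."""


class InputError(ClampscreenError):
    """A required pipeline input is missing or inconsistent."""


class ConfigError(ClampscreenError):
    """Pipeline configuration failed schema validation."""
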