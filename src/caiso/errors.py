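"""Exception hierarchy for the caiso package."""


class CaisoError(Exception):
    """Base class for all package errors."""


class DataError(CaisoError):
    """Invalid or non-finite input data (bad intensity, bad ABI, bad enum value)."""


class StructureError(CaisoError):
    """Analysis-session ordering violation (missing blank or bracketing standard)."""


class ReductionError(CaisoError):
    """Numerically invalid reduction step (nonpositive ratio, missing factors)."""


class CalibrationError(CaisoError):
    """Degenerate concentration calibration (singular design)."""


class ConfigError(CaisoError):
    """Unknown scale name, bad threshold, or malformed configuration."""


class CollinearityError(CaisoError):
    """Rank-deficient regression design; carries the offending term names."""

    def __init__(self, message: str, terms: list[str] | None = None):
        super().__init__(message)
        self.terms = terms or []


class AnalysisError(CaisoError):
    """Statistical analysis cannot proceed (single-class labels, all-missing variable)."""


class GenerationError(CaisoError):
    """Synthetic-data specification is infeasible."""


class SpecificationError(CaisoError):
    """Mass-balance scenario violates its invariants (fractions not summing to 1)."""
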