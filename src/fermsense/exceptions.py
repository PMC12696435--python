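"""Exception types shared across the package."""


class FermsenseError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(FermsenseError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateSignalError(FermsenseError, ValueError):
    """Smoothed transmission at or below the inverse-transform guard;
    the culture is opaque beyond the probe's usable range (or the
    sensor dropped out)."""


class SingularDesignError(FermsenseError, ValueError):
    """The calibration design matrix is rank deficient."""

    def __init__(self, collinear_features):
        self.collinear_features = list(collinear_features)
        super().__init__(
            "singular calibration design; collinear/degenerate features: "
            + ", ".join(self.collinear_features)
        )


class SchemaError(FermsenseError, ValueError):
    """Feature names or file columns do not match the expected schema."""


class ParseError(FermsenseError, ValueError):
    """A data file failed schema validation; `row` is the 1-based file
    line (header = line 1) when the failure is localized."""

    def __init__(self, message, row=None):
        self.row = row
        if row is not None:
            message = f"{message} (line {row})"
        super().__init__(message)


class ModelVersionError(FermsenseError, ValueError):
    """Persisted model artifact has an incompatible schema version."""


class ClosedRunError(FermsenseError, RuntimeError):
    """Controller stepped after the run was closed by harvest."""
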