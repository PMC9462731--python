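"""Exception hierarchy for the cfmr package."""


class CfmrError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CfmrError, ValueError):
    """Invalid scenario, selection, or run configuration."""


class DegenerateInstrumentError(CfmrError):
    """The instrument carries no usable variation (zero variance or
    intercept-only predictor where identification is required)."""


class RankDeficiencyError(CfmrError):
    """The instrument cross-product matrix is singular.

    Carries the offending column indices in ``columns``.
    """

    def __init__(self, message: str, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class InstrumentConstructionError(CfmrError):
    """Cross-fitted instrument construction failed (no identification)."""
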