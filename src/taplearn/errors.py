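"""Exception hierarchy used across the package.

The CLI maps these onto distinct exit codes so that shell pipelines can
tell schema problems from statistical ones.
"""


class TapLearnError(Exception):
    """Base class for all package-specific errors."""


class DesignError(TapLearnError):
    """Invalid factorial design (non-binary factor, aliased effects, ...)."""


class SchemaError(TapLearnError):
    """Malformed input table: missing columns, duplicates, unknown levels."""


class IdentifiabilityError(TapLearnError):
    """Too little data to identify the requested model."""


class InitializationError(TapLearnError):
    """MCMC could not find a finite starting density."""


class DiagnosticsError(TapLearnError):
    """Not enough retained draws for convergence diagnostics."""


class DegenerateInputError(TapLearnError):
    """Statistic undefined on this input (zero variance, n too small)."""


class ReportError(TapLearnError):
    """Results bundle is missing sections required for the report."""
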