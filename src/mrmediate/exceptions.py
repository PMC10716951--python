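"""Exception hierarchy for MR analyses.

Data problems that should abort a run raise subclasses of
:class:`MRError`; recoverable per-SNP problems never raise — they are
recorded as drop reasons on the harmonized set instead.
"""


class MRError(Exception):
    """Base class for all package errors."""


class FormatError(MRError):
    """A summary-statistics file does not match the expected layout."""


class ValidationError(MRError):
    """Input values violate a documented invariant."""


class EmptyInstrumentError(MRError):
    """No variant passed the instrument-selection thresholds for a trait."""


class HarmonizationError(MRError):
    """Exposure and outcome tables share no usable variants."""


class DegenerateInstrumentError(MRError):
    """A Wald ratio was requested for a variant with zero exposure effect."""


class InsufficientInstrumentsError(MRError):
    """An estimator needs more variants than the harmonized set provides."""


class UnderIdentifiedError(MRError):
    """The multivariable instrument set is too small for the exposure count."""


class CollinearExposuresError(MRError):
    """The MVMR design matrix is numerically rank deficient."""

    def __init__(self, condition_number: float):
        self.condition_number = condition_number
        super().__init__(
            f"exposure effect columns are collinear "
            f"(condition number {condition_number:.3g} exceeds 1e8)"
        )


class UndefinedProportionError(MRError):
    """Mediation proportion requested with a zero total effect."""
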