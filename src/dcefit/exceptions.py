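"""Exception hierarchy for dcefit."""


class DcefitError(Exception):
    """Base class for all dcefit errors."""


class ModelError(DcefitError, ValueError):
    """Invalid kinetic-model inputs."""


class InvalidInfusionWindowError(ModelError):
    """Infusion end time does not follow the start time (t1 <= t0)."""


class CoincidentRateError(ModelError):
    """Rate constants produce (near-)coincident exponents in the closed forms."""


class OracleFailureError(DcefitError, RuntimeError):
    """The ODE reference integrator failed (test infrastructure only)."""


class OutOfBoundsError(DcefitError, ValueError):
    """Natural-unit parameter vector lies outside its box constraints."""


class DegenerateArterialDataError(DcefitError, ValueError):
    """Arterial concentration series is all-zero or contains non-finite values."""


class EmptyBatchError(DcefitError, ValueError):
    """No voxels survive exclusion; nothing to fit."""


class EmptyRoiError(DcefitError, ValueError):
    """ROI contains no non-excluded voxels."""


class EmptyMapError(DcefitError, ValueError):
    """Parameter map contains no finite values."""


class DimensionError(DcefitError, ValueError):
    """Input arrays have inconsistent shapes; message names the offending axis."""


class UndefinedBaselineError(DcefitError, ZeroDivisionError):
    """Percent change is undefined for a zero baseline."""
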