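"""Exception hierarchy for the ramancode package."""


class RamanCodeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RamanCodeError, ValueError):
    """A code scheme, plan, or run configuration is internally inconsistent."""


class InfeasiblePlanError(ConfigurationError):
    """Amino-group allocation fractions sum to more than 1."""


class SequenceParseError(RamanCodeError, ValueError):
    """A peptide string does not match the scheme template or alphabet."""


class SpectrumParseError(RamanCodeError, ValueError):
    """A spectrum file could not be parsed."""


class GridMismatchError(RamanCodeError, ValueError):
    """Spectra expected on a common wavenumber grid are not."""


class RangeError(RamanCodeError, ValueError):
    """A requested wavenumber window falls outside the spectrum grid."""


class ParameterError(RamanCodeError, ValueError):
    """Invalid preprocessing or quantification parameters."""


class CalibrationError(RamanCodeError, ValueError):
    """Calibration standards are incomplete or not level-monotone."""


class LowSignalError(RamanCodeError, ValueError):
    """A reference peak is below the noise floor; the bead is undecodable."""


class InvalidBaselineError(RamanCodeError, ValueError):
    """A before-treatment ratio of zero makes the relative change undefined."""


class IncompletePanelError(RamanCodeError, ValueError):
    """A survivability panel is missing a condition before any failure."""


class EmptyScreenError(RamanCodeError, ValueError):
    """Screening statistics requested on an empty collection of beads."""
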