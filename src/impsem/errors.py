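"""Exception hierarchy shared by all impsem modules."""


class ImpsemError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(ImpsemError):
    """Non-physical impactor geometry (e.g. non-positive orifice diameter)."""


class InvalidDiameterError(ImpsemError):
    """Particle diameter outside the physically valid domain."""


class NoSolutionError(ImpsemError):
    """Root finding failed to bracket a solution."""


class PairingError(ImpsemError):
    """Measurement series that must refer to the same setpoint do not."""


class InsufficientDataError(ImpsemError):
    """Too few data points for the requested estimate or fit."""


class FitFailureError(ImpsemError):
    """Nonlinear least squares did not converge."""


class SchemaError(ImpsemError):
    """Tabular input violates the documented column schema."""


class ManifestError(ImpsemError):
    """Micrograph manifest is inconsistent or incomplete."""


class CoverageError(ImpsemError):
    """Requested ranges/edges do not overlap the available data."""


class CalibrationError(ImpsemError):
    """Concentration calibration is impossible on the given sample."""


class ConfigError(ImpsemError):
    """Invalid configuration value or unknown configuration key."""
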