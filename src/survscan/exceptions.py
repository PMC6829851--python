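"""Exception types shared across survscan."""


class SurvscanError(Exception):
    """Base class for survscan errors."""


class NonIdentifiableError(SurvscanError, ValueError):
    """A model covariate carries no information (e.g. constant column)."""


class AlignmentError(SurvscanError, ValueError):
    """Individual ids of genotypes, phenotype and covariates do not match."""


class CalibrationError(SurvscanError, RuntimeError):
    """Automatic calibration (intercept or MAF spectrum) failed to bracket."""


class SimulationError(SurvscanError, RuntimeError):
    """A simulated cohort is degenerate (e.g. truncation removed everyone)."""


class ConfigurationError(SurvscanError, ValueError):
    """Invalid simulation or scan configuration."""
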