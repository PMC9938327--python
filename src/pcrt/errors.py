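"""Exception types shared across the package."""


class PcrtError(Exception):
    """Base class for all package-specific errors."""


class CohortParseError(PcrtError):
    """A cohort file could not be parsed; the message names the offending record."""


class DuplicatePatientIdError(CohortParseError):
    """Two records in one cohort share a patient_id."""


class ConfigurationError(PcrtError):
    """A required configuration object is missing or malformed."""
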