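"""Exception types shared across the package."""


class PvSignalError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PvSignalError):
    """A required column or table is missing from an input file."""


class MeddraLookupError(PvSignalError, LookupError):
    """A Preferred Term has no entry in the PT -> SOC dictionary."""


class SampleSizeError(PvSignalError, ValueError):
    """A sample is too small for the requested fit."""


class FitError(PvSignalError, ValueError):
    """A model fit is impossible on the given data (degenerate sample)."""


class MRInputError(PvSignalError, ValueError):
    """Invalid or incomplete Mendelian-randomization inputs."""


class HarmonizationError(MRInputError):
    """Harmonization produced no usable instruments.

    ``counts`` records how many variants were lost at each step.
    """

    def __init__(self, message: str, counts: dict | None = None):
        super().__init__(message)
        self.counts = dict(counts or {})


class NoSharedVariantsError(HarmonizationError):
    """Exposure and outcome summary statistics share no variant identifiers."""


class NoInstrumentsAfterHarmonizationError(HarmonizationError):
    """Variants were shared but every one was removed during harmonization."""
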