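"""Exception types shared across the package."""


class HaplotraitError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(HaplotraitError, ValueError):
    """A simulation or run configuration is internally inconsistent."""


class SingularDesignError(HaplotraitError, ValueError):
    """A regression design matrix is rank deficient."""


class UndefinedFrequencyError(HaplotraitError, ValueError):
    """An ancestry has zero total painting weight, so its allele frequency
    is undefined."""


class MatchingError(HaplotraitError, ValueError):
    """A trait SNP has no frequency-matched SNP in the null pool."""
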