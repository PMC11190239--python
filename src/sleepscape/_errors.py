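"""Exception hierarchy for the sleepscape pipeline."""


class SleepscapeError(Exception):
    """Base class for all sleepscape errors."""


class ConfigError(SleepscapeError, ValueError):
    """Invalid configuration (non-stochastic matrix, bad fractions, ...)."""


class GenerationError(SleepscapeError, RuntimeError):
    """An archetype's parameters cannot be realised as a hypnogram."""


class DataError(SleepscapeError, ValueError):
    """Malformed or inconsistent input data."""
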