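"""Typed errors raised at the package boundary."""


class ReaderBenchError(Exception):
    """Base class for all readerbench errors."""


class SchemaError(ReaderBenchError):
    """A table is missing a required column or has an unknown schema."""


class ValidationError(ReaderBenchError):
    """A row violates a field invariant (range, enum, duplicate key)."""


class ConfigError(ReaderBenchError):
    """A study or benchmark configuration is internally inconsistent."""


class InferenceError(ReaderBenchError):
    """An ROC quantity is undefined for the given data (e.g. one class only)."""
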