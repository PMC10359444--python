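"""Exception types shared across the pipeline."""


class DkdArulesError(Exception):
    """Base class for all package errors."""


class ValidationError(DkdArulesError, ValueError):
    """A profile or record field violates an invariant."""


class SchemaError(DkdArulesError, ValueError):
    """A cohort CSV does not conform to the documented schema."""


class IndeterminateError(DkdArulesError, ValueError):
    """A classification cannot be made because every input field is missing."""


class ClassificationError(DkdArulesError, ValueError):
    """An outcome cannot be classified (e.g. no follow-up eGFR in the window)."""


class ThresholdError(DkdArulesError, ValueError):
    """A percentile threshold cannot be computed for a (factor, sex) pair."""


class ConfigError(DkdArulesError, ValueError):
    """An unknown scheme, cohort kind or configuration key was supplied."""


class PipelineError(DkdArulesError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
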