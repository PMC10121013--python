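"""Exception hierarchy shared across the pipeline stages."""


class SpringLayerError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SpringLayerError):
    """A generator or pipeline configuration violates its invariants."""


class GenerationError(SpringLayerError):
    """Synthetic-data generation failed for a specific trial."""


class EstimationError(SpringLayerError):
    """A model fit could not be computed (rank deficiency, no df, no convergence)."""


class PipelineError(SpringLayerError):
    """A pipeline stage produced no usable output (e.g. zero valid trials)."""


class UsageError(SpringLayerError):
    """An operation was called with an incompatible model or mode."""
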