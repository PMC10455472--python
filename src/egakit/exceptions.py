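"""Exception hierarchy."""


class EgakitError(Exception):
    """Base class for all egakit errors."""


class SpecificationError(EgakitError):
    """An invalid factor-model specification (non-PSD factor correlations,
    negative uniqueness, malformed loadings)."""


class EstimationError(EgakitError):
    """Network estimation failed (singular input, solver failure, or an
    entire regularization path with no usable fit)."""


class PipelineError(EgakitError):
    """The refinement workflow cannot proceed (e.g. removal would leave
    fewer than three items)."""
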