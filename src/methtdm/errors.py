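"""Exception types shared across the pipeline."""


class MethTDMError(Exception):
    """Base class for all package-specific errors."""


class DegenerateInputError(MethTDMError, ValueError):
    """A statistic was requested on data with no usable variation
    (constant vector, zero pooled variance, single degree value)."""


class EmptyMatrixError(MethTDMError, ValueError):
    """An operation removed or received every row of a matrix."""


class UnclassifiableMotifError(MethTDMError, ValueError):
    """The baseline correlation is too weak to call a regulation direction."""


class ConfigError(MethTDMError, ValueError):
    """A simulation or pipeline configuration violates its invariants."""
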