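"""Exception hierarchy shared across the pipeline stages."""


class CCMirNetError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(CCMirNetError, ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class ValidationError(CCMirNetError, ValueError):
    """An input table or parameter fails a precondition."""


class NormalizationError(CCMirNetError, ValueError):
    """A sample cannot be normalized (zero totals, zero percentiles, ...)."""


class DegenerateInputError(CCMirNetError, ValueError):
    """A statistical routine received input with no usable signal."""


class ReferenceError_(CCMirNetError, KeyError):
    """A planted effect or record refers to an unknown feature id."""


class ConsistencyError(CCMirNetError, ValueError):
    """Cross-file identifiers do not line up (samples, subjects, pairs)."""
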