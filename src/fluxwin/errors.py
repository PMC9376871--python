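"""Exception types shared across the pipeline."""


class ParameterError(ValueError):
    """A parameter is outside its valid domain."""


class ConsistencyError(ValueError):
    """Two objects that must agree (spec vs. frames, phantom vs. design) do not."""


class ConstraintError(ValueError):
    """A randomized design cannot satisfy its ordering/ratio constraints."""


class DesignError(ValueError):
    """A design matrix is unusable (e.g. rank deficient)."""


class GeometryError(ValueError):
    """Phantom geometry is invalid (e.g. overlapping ROI definitions)."""


class InsufficientDataError(ValueError):
    """Not enough usable data to estimate the requested quantity."""
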