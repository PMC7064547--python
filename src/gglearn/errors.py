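"""Exception hierarchy shared across the package."""


class GGLearnError(Exception):
    """Base class for all package-specific errors."""


class ParameterDomainError(GGLearnError, ValueError):
    """A model parameter lies outside its admissible domain."""


class DataError(GGLearnError, ValueError):
    """Input data violate a structural contract (keys, codes, lengths)."""


class DegenerateInputError(GGLearnError, ValueError):
    """Input is formally valid but carries no information for the requested
    estimate (constant vector, single-category ordinal, one-class labels)."""


class CalibrationError(GGLearnError, ValueError):
    """A requested generator calibration target is infeasible."""


class ConfigError(GGLearnError, ValueError):
    """A configuration object fails its own invariants."""


class StratificationError(GGLearnError, ValueError):
    """Cross-validation folds cannot keep both classes represented."""
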