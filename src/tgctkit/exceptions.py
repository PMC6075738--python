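"""Exception hierarchy shared across the toolkit."""


class TGCTKitError(Exception):
    """Base class for all toolkit errors."""


class FormatError(TGCTKitError):
    """A file does not conform to the expected tabular dialect."""


class ValidationError(TGCTKitError):
    """Input values violate a documented invariant."""


class ConfigError(TGCTKitError):
    """A run or simulation configuration is infeasible or incomplete."""


class EstimationError(TGCTKitError):
    """Too little usable data to produce an estimate."""


class UsageError(TGCTKitError):
    """An operation was invoked outside its documented precondition."""
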