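"""Exception hierarchy shared across the package."""


class RGBFVCError(Exception):
    """Base class for all package-specific errors."""


class RasterIOError(RGBFVCError):
    """A raster file could not be read or written, or has an unusable layout."""


class ContractError(RGBFVCError, ValueError):
    """An operation was called with inputs violating its preconditions."""


class DegenerateDistributionError(ContractError):
    """Endpoint estimation found no spread between the soil and vegetation tails."""
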