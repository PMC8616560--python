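"""Exception hierarchy for the golgikin pipeline."""


class GolgikinError(Exception):
    """Base class for all golgikin errors."""


class InvalidParameterError(GolgikinError, ValueError):
    """A parameter violates its documented constraint (e.g. even window, sigma <= 0)."""


class ConfigurationError(GolgikinError, ValueError):
    """A simulation or pipeline configuration is internally inconsistent."""


class DegenerateImageError(GolgikinError, ValueError):
    """An image has too little structure for the requested operation (e.g. constant image for Otsu)."""


class DegenerateObjectError(GolgikinError, ValueError):
    """A segmented object is unusable (e.g. zero integrated intensity)."""


class DegenerateTraceError(GolgikinError, ValueError):
    """A fluorescence trace is flat in some channel and cannot be normalized."""


class InsufficientDataError(GolgikinError, ValueError):
    """Too few tracks/cells for the requested summary (e.g. < 2 tracks for averaging)."""
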