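"""Exception hierarchy shared across the SAPM pipeline."""


class SapmapError(Exception):
    """Base class for all sapmap errors."""


class ConfigError(SapmapError):
    """Invalid configuration (category scheme gaps, bad paths, bad grid)."""


class RegisterError(SapmapError):
    """Invalid fleet-register data (bad lengths, crew entries, links)."""


class CRSError(SapmapError):
    """Input geometry is not in a projected, metre-based CRS."""


class GeometryError(SapmapError):
    """Unrepairable or degenerate (zero-area) response geometry."""


class UnsampledCategoryError(SapmapError):
    """A vessel category needed downstream has no interviewed vessels."""


class UnsampledGearError(SapmapError):
    """A gear type with estimated crew has no interviews fleet-wide."""


class GridMismatchError(SapmapError):
    """Two rasters do not share an identical grid specification."""


class GridExtentError(SapmapError):
    """A polygon falls outside the target grid extent."""


class SyntheticError(SapmapError):
    """Infeasible synthetic-scenario configuration."""
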