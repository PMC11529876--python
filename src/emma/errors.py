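"""Exception hierarchy shared across the pipeline stages."""


class EmmaError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(EmmaError):
    """Invalid parameters, geometry that does not fit, or a bad config file."""


class StitchError(EmmaError):
    """Pairwise registration or global layout solving failed."""


class PyramidError(EmmaError):
    """Deep Zoom pyramid construction or I/O failed."""


class FormatError(EmmaError):
    """A file (descriptor XML, sidecar, layout table) could not be parsed."""


class SiteError(EmmaError):
    """Atlas page generation failed."""
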