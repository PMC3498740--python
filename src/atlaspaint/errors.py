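"""Exception hierarchy for atlaspaint."""


class AtlasPaintError(Exception):
    """Base class for all atlaspaint errors."""


class TemplateError(AtlasPaintError):
    """Malformed or inconsistent expression template."""


class LegendError(AtlasPaintError):
    """Malformed legend or legend/labelfield inconsistency."""


class ImageError(AtlasPaintError):
    """Problem with a source/labelfield image pair."""


class NetworkFormatError(AtlasPaintError):
    """Unparseable or inconsistent network file."""


class RenderError(AtlasPaintError):
    """Failure while producing a static export."""
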