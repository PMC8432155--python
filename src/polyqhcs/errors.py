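"""Exception hierarchy shared across the pipeline."""


class PolyqhcsError(Exception):
    """Base class for all package errors."""


class InputError(PolyqhcsError):
    """Invalid user-supplied input (bad arguments, malformed tables)."""


class PlacementError(PolyqhcsError):
    """Synthetic object placement failed after bounded retries."""


class DegenerateHistogramError(PolyqhcsError):
    """Otsu thresholding on a histogram with no between-class variance."""


class StructuralError(PolyqhcsError):
    """A required structural element (e.g. an injection phase) is missing."""


class FitQualityError(PolyqhcsError):
    """A kinetic fit failed its quality gate."""


class DesignError(PolyqhcsError):
    """A statistical design is degenerate (too few groups or replicates)."""
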