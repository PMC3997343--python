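"""Exception types raised across the pipeline stages."""


class InsectHullError(Exception):
    """Base class for all pipeline errors."""


class InsufficientMarkersError(InsectHullError):
    """Fewer than four fiducial markers were detected in a view."""


class DegenerateConfigurationError(InsectHullError):
    """Marker geometry is rank-deficient (e.g. collinear image points)."""


class InvalidScheduleError(InsectHullError):
    """An acquisition plan was requested with zero or inconsistent steps."""


class MissingCaptureError(InsectHullError):
    """A plan slot has no matching image file on disk."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"missing capture(s): {self.missing[:10]}"
                         + (" ..." if len(self.missing) > 10 else ""))


class OrphanFileError(InsectHullError):
    """An image file matches no slot of the acquisition plan."""

    def __init__(self, orphans):
        self.orphans = list(orphans)
        super().__init__(f"orphan file(s): {self.orphans[:10]}"
                         + (" ..." if len(self.orphans) > 10 else ""))


class EmptySilhouetteError(InsectHullError):
    """No foreground pixels survive segmentation."""


class NoViewsError(InsectHullError):
    """Carving requested with an empty view list."""


class DegenerateGridError(InsectHullError):
    """Occupancy grid is all-empty or all-occupied; no surface exists."""


class AtlasOverflowError(InsectHullError):
    """Mesh faces cannot be packed into the requested atlas size."""


class UnsupportedFormatError(InsectHullError):
    """Mesh export requested in a format the package does not write."""


class OverlappingPrimitivesError(InsectHullError):
    """Scene primitives overlap; the analytic volume would double-count."""
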