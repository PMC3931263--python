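"""Exception hierarchy shared across the package."""


class PatchkitError(Exception):
    """Base class for all package-specific errors."""


class RegionError(PatchkitError, IndexError):
    """A cursor region is empty, inverted, or out of the trace's bounds."""


class IncompatibleTracesError(PatchkitError, ValueError):
    """Traces cannot be combined (mismatched dt, units, or lengths)."""


class FormatError(PatchkitError, ValueError):
    """A file could not be parsed as the expected on-disk format."""


class MeasurementUndefinedError(PatchkitError, ValueError):
    """A measurement has no defined value on this trace/region.

    Carries the name of the failed measurement so batch drivers can report
    which cursor placement was at fault.
    """

    def __init__(self, measurement: str, detail: str = ""):
        self.measurement = measurement
        msg = f"measurement '{measurement}' undefined"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class InitializationError(PatchkitError, ValueError):
    """Automatic initial-parameter estimation failed for a model fit."""


class FitError(PatchkitError, RuntimeError):
    """The least-squares search produced non-finite values or diverged."""


class DetectionError(PatchkitError, RuntimeError):
    """Event-detection bootstrap failed (e.g. no candidate peaks)."""
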