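"""Exception hierarchy used across the package."""


class RegsecError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(RegsecError):
    """A simulation or analysis configuration violates its invariants."""


class ProtocolError(RegsecError):
    """Stimulation-protocol metadata is missing, malformed or inconsistent
    with the recording (e.g. a window extending past the last frame)."""


class ClippedRoiError(RegsecError):
    """A requested ROI would cross the image border."""


class DegenerateBaselineError(RegsecError):
    """The baseline fluorescence F0 is non-positive, so dF/F0 is undefined."""


class AnalysisError(RegsecError):
    """A quantification step received input it cannot operate on
    (empty mask, missing window, too few samples, ...)."""
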