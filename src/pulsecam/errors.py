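"""Exception hierarchy.

Every error raised by the library derives from :class:`PulseCamError` so
callers (and the CLI) can catch library failures with a single handler.
"""


class PulseCamError(Exception):
    """Base class for all pulsecam errors."""


class WaveformFormatError(PulseCamError):
    """A waveform file could not be parsed or violates format preconditions."""


class SegmentationError(PulseCamError):
    """Pulse segmentation failed (e.g. fewer than two diastolic feet found)."""


class DegenerateInputError(PulseCamError):
    """The input carries no usable signal (e.g. a constant pulse)."""


class ParameterError(PulseCamError):
    """A configuration parameter is out of its admissible range."""


class PeakDetectionError(PulseCamError):
    """No late-systolic feature (second peak or shoulder) could be located."""


class OptimizationError(PulseCamError):
    """The representative-waveform minimization hit a non-finite objective."""


class UndefinedPhaseError(PulseCamError):
    """A DFT bin has negligible magnitude, so its phase angle is undefined."""
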