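"""Exception hierarchy shared across the pipeline stages."""


class SlideQuantError(Exception):
    """Base class for all slidequant errors."""


class InvalidParameterError(SlideQuantError, ValueError):
    """A parameter violates its documented constraint."""


class ShapeMismatchError(SlideQuantError, ValueError):
    """Two grids that must share a shape do not."""


class DegenerateGeometryError(SlideQuantError, ValueError):
    """The requested tissue geometry cannot fit the slide."""


class EmptyImageError(SlideQuantError, ValueError):
    """An operation received an empty (zero-sized) image."""


class EmptyInputError(SlideQuantError, ValueError):
    """An operation that requires a nonempty input received an empty one."""


class MissingChannelError(SlideQuantError, ValueError):
    """A slide file lacks one of the required channel roles."""


class MissingCalibrationError(SlideQuantError, ValueError):
    """No pixel-size calibration available from metadata or config."""


class StageError(SlideQuantError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
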