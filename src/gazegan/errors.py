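"""Exception hierarchy shared across the package."""


class GazeGanError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GazeGanError):
    """Input table is missing required columns or is unparsable."""


class InsufficientDataError(GazeGanError):
    """Fewer valid samples than the operation requires."""


class DuplicateTimestampError(GazeGanError):
    """Timestamps are not strictly increasing after sorting."""


class ZeroTimeGapError(GazeGanError):
    """Consecutive samples share a timestamp; velocity is undefined."""

    def __init__(self, index: int):
        super().__init__(f"zero time gap between samples {index} and {index + 1}")
        self.index = index


class DegenerateRangeError(GazeGanError):
    """A constant series cannot be min-max normalized or binned."""


class ConfigError(GazeGanError):
    """Invalid configuration value or unknown configuration key."""


class SpecError(GazeGanError):
    """Architecture specification is internally inconsistent."""


class DivergenceError(GazeGanError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, batch: int, which: str):
        super().__init__(f"non-finite {which} loss at epoch {epoch}, batch {batch}")
        self.epoch = epoch
        self.batch = batch
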