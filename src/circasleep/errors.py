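"""Exception types shared across the package."""


class CircasleepError(Exception):
    """Base class for package errors."""


class ConfigurationError(CircasleepError, ValueError):
    """Invalid configuration (epoching, transition topology, parameters)."""


class FormatError(CircasleepError, ValueError):
    """Malformed or inconsistent on-disk data (EDF headers, CSV columns)."""


class StateAbsentError(CircasleepError, ValueError):
    """A vigilance state required by a metric does not occur in the hypnogram."""


class StageError(CircasleepError, RuntimeError):
    """A pipeline stage failed; carries the stage name and animal id."""

    def __init__(self, stage: str, animal: str | None, message: str):
        self.stage = stage
        self.animal = animal
        super().__init__(f"stage '{stage}'"
                         + (f", animal '{animal}'" if animal else "")
                         + f": {message}")
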