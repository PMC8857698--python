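"""Exception hierarchy for the carenet pipeline."""


class CarenetError(Exception):
    """Base class for all carenet errors."""


class ConfigurationError(CarenetError):
    """A configuration object violates its invariants; names the offending field."""


class DataError(CarenetError):
    """Input data violates the documented schema (e.g. unknown encounter ID)."""


class ContractError(CarenetError):
    """A precondition of an operation was violated by the caller."""


class GenerationError(CarenetError):
    """The synthetic generator cannot honour its configuration."""


class StageError(CarenetError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
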