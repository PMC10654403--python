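"""Exception hierarchy for depotmetry."""


class DepotmetryError(Exception):
    """Base class for all depotmetry errors."""


class ConfigError(DepotmetryError):
    """Invalid or inconsistent session / phantom configuration."""


class FormatError(DepotmetryError):
    """Malformed or inconsistent input data (shapes, headers, ordering)."""


class InsufficientReferencesError(FormatError):
    """Fewer than two volumes: no pre-infusion references available."""


class StageError(DepotmetryError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
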