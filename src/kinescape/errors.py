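"""Exception hierarchy.

All package-raised errors derive from :class:`KinescapeError` so callers can
catch analysis failures without masking programming errors.
"""


class KinescapeError(Exception):
    """Base class for all errors raised by kinescape."""


class TopologyError(KinescapeError):
    """Structure/topology input is malformed or internally inconsistent."""


class SelectionError(KinescapeError):
    """An atom selection resolved to nothing or to an invalid set."""


class FeatureError(KinescapeError):
    """Order-parameter evaluation failed."""


class EstimationError(KinescapeError):
    """Markov-model construction failed (counting, trimming, normalisation)."""


class NumericalError(KinescapeError):
    """A numerical contract was violated (underflow, instability, bad dt)."""


class ConfigError(KinescapeError):
    """Pipeline configuration is invalid."""


class StageError(KinescapeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
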